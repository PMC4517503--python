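"""Reader/consensus RMSE, Bland-Altman and consensus standard error."""

import numpy as np
import pytest

from lvconsensus import (
    LVFunction,
    bland_altman,
    build_function_matrices,
    consensus_rmse,
    consensus_se,
    reader_rmse,
    summarize_cohort,
)
from lvconsensus.agreement_stats import (
    AgreementError,
    FunctionMatrix,
    all_reader_rmse,
)


def matrix(values, consensus=None, name="EDV"):
    values = np.asarray(values, dtype=float)
    R, N = values.shape
    return FunctionMatrix(name=name, readers=[f"r{i}" for i in range(R)],
                          cases=[f"c{k}" for k in range(N)], values=values,
                          consensus=consensus)


class TestReaderRMSE:
    def test_identical_readers_zero(self):
        m = matrix(np.full((4, 3), 150.0))
        assert np.all(all_reader_rmse(m) == 0.0)

    def test_two_readers_one_case(self):
        m = matrix([[100.0], [110.0]])
        assert reader_rmse(m, 0) == pytest.approx(10.0, abs=1e-12)
        assert reader_rmse(m, 1) == pytest.approx(10.0, abs=1e-12)

    def test_hand_evaluated_three_by_two(self):
        m = matrix([[100, 200], [110, 190], [90, 210]])
        # reader 1 differs by 10 from both others on both cases
        assert reader_rmse(m, 0) == pytest.approx(10.0, abs=1e-12)

    def test_single_reader_rejected(self):
        with pytest.raises(AgreementError):
            matrix([[100.0, 110.0]])

    def test_case_order_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(150, 20, (5, 8))
        m = matrix(v)
        perm = rng.permutation(8)
        m2 = matrix(v[:, perm])
        assert np.allclose(all_reader_rmse(m), all_reader_rmse(m2))


class TestConsensusRMSE:
    def test_consensus_equal_to_readers_zero(self):
        m = matrix(np.full((3, 4), 90.0), consensus=np.full(4, 90.0))
        assert consensus_rmse(m) == 0.0

    def test_two_readers_midpoint(self):
        m = matrix([[100.0], [110.0]], consensus=[105.0])
        assert consensus_rmse(m) == pytest.approx(5.0, abs=1e-12)

    def test_mean_consensus_never_beaten_by_a_reader(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            v = rng.normal(150, 25, (6, 10))
            m = matrix(v, consensus=v.mean(axis=0))
            assert consensus_rmse(m) <= all_reader_rmse(m).min() + 1e-12

    def test_reader_order_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.normal(100, 10, (5, 6))
        cons = v.mean(axis=0)
        e1 = consensus_rmse(matrix(v, consensus=cons))
        e2 = consensus_rmse(matrix(v[::-1], consensus=cons))
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_missing_consensus_row_errors(self):
        with pytest.raises(AgreementError, match="consensus"):
            consensus_rmse(matrix([[1.0], [2.0]]))


class TestBlandAltman:
    def test_reader_equals_consensus(self):
        v = np.array([[100.0, 120.0, 140.0]])
        m = matrix(np.vstack([v, v + 5]), consensus=v[0])
        ba = bland_altman(m, 0)
        assert ba.bias == 0.0 and ba.precision == 0.0

    def test_constant_offset(self):
        m = matrix([[110.0, 120.0, 130.0], [95.0, 105.0, 115.0]],
                   consensus=[100.0, 110.0, 120.0])
        ba = bland_altman(m, 0)
        assert ba.bias == pytest.approx(10.0)
        assert ba.precision == 0.0
        assert (ba.lower_limit, ba.upper_limit) == (10.0, 10.0)

    def test_hand_sd_and_limits(self):
        m = matrix([[95.0, 100.0, 105.0], [100.0, 100.0, 100.0]],
                   consensus=[100.0, 100.0, 100.0])
        ba = bland_altman(m, 0)  # differences -5, 0, 5
        assert ba.bias == pytest.approx(0.0)
        assert ba.precision == pytest.approx(5.0)
        assert ba.lower_limit == pytest.approx(-9.8)
        assert ba.upper_limit == pytest.approx(9.8)

    def test_single_case_precision_undefined(self):
        m = matrix([[100.0], [105.0]], consensus=[102.0])
        with pytest.raises(AgreementError, match="two cases"):
            bland_altman(m, 0)

    def test_constant_shift_moves_bias_only(self):
        rng = np.random.default_rng(2)
        v = rng.normal(150, 15, (4, 9))
        cons = v.mean(axis=0)
        m = matrix(v, consensus=cons)
        shifted = v.copy()
        shifted[2] += 7.5
        m2 = matrix(shifted, consensus=cons)
        ba, ba2 = bland_altman(m, 2), bland_altman(m2, 2)
        assert ba2.bias == pytest.approx(ba.bias + 7.5)
        assert ba2.precision == pytest.approx(ba.precision)


class TestConsensusSE:
    def test_zero_when_readers_equal_consensus(self):
        m = matrix(np.full((5, 2), 80.0), consensus=np.full(2, 80.0))
        assert consensus_se(m, 0) == 0.0

    def test_symmetric_deviations(self):
        m = matrix([[102.0], [98.0], [102.0], [98.0]], consensus=[100.0])
        # RMS deviation 2, R = 4 -> SE = 2 / sqrt(4) = 1
        assert consensus_se(m, 0) == pytest.approx(1.0, abs=1e-12)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(4)
        v = rng.normal(120, 18, (7, 5))
        cons = rng.normal(120, 5, 5)
        m = matrix(v, consensus=cons)
        for k in range(5):
            acc = 0.0
            for j in range(7):
                acc += (v[j, k] - cons[k]) ** 2
            expected = np.sqrt(acc / 7) / np.sqrt(7)
            assert consensus_se(m, k) == pytest.approx(expected, rel=1e-12)


class TestSummarizeCohort:
    @staticmethod
    def functions(values_by_index, consensus_by_index, readers, cases):
        out = []
        for i, r in enumerate(readers):
            for k, c in enumerate(cases):
                out.append(LVFunction(
                    case_id=c, source_id=r,
                    edv_ml=values_by_index["EDV"][i, k],
                    esv_ml=values_by_index["ESV"][i, k],
                    lvm_g=values_by_index["LVM"][i, k],
                    ef_pct=values_by_index["EF"][i, k]))
        for k, c in enumerate(cases):
            out.append(LVFunction(
                case_id=c, source_id="consensus",
                edv_ml=consensus_by_index["EDV"][k],
                esv_ml=consensus_by_index["ESV"][k],
                lvm_g=consensus_by_index["LVM"][k],
                ef_pct=consensus_by_index["EF"][k]))
        return out

    def test_identical_readers_all_statistics_zero(self):
        readers, cases = ["a", "b", "c"], ["c1", "c2"]
        vals = {n: np.full((3, 2), 100.0) for n in ("EDV", "ESV", "LVM", "EF")}
        cons = {n: np.full(2, 100.0) for n in vals}
        matrices = build_function_matrices(
            self.functions(vals, cons, readers, cases))
        reports = summarize_cohort(matrices)
        for rep in reports.values():
            assert rep.e_c == 0.0
            assert np.all(rep.e_i == 0.0)
            assert np.all(rep.bias == 0.0)
            assert np.all(rep.precision == 0.0)

    def test_reader_relabeling_permutes_reader_outputs_only(self):
        rng = np.random.default_rng(6)
        readers, cases = ["a", "b", "c", "d"], ["c1", "c2", "c3"]
        vals = {n: rng.normal(100, 10, (4, 3)) for n in ("EDV", "ESV", "LVM", "EF")}
        cons = {n: vals[n].mean(axis=0) for n in vals}
        rep1 = summarize_cohort(build_function_matrices(
            self.functions(vals, cons, readers, cases)))["EDV"]
        relabeled = ["d", "c", "b", "a"]
        rep2 = summarize_cohort(build_function_matrices(
            self.functions(vals, cons, relabeled, cases)))["EDV"]
        assert rep2.e_c == pytest.approx(rep1.e_c, rel=1e-12)
        assert sorted(rep2.e_i) == pytest.approx(sorted(rep1.e_i), rel=1e-12)

    def test_incomplete_grid_rejected(self):
        funcs = [
            LVFunction("c1", "a", 100, 50, 90, 50),
            LVFunction("c1", "b", 100, 50, 90, 50),
            LVFunction("c2", "a", 100, 50, 90, 50),
        ]
        with pytest.raises(AgreementError, match="missing cell"):
            build_function_matrices(funcs)
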