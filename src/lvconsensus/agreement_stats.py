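"""Inter-reader and reader-consensus agreement statistics.

For a functional index F (EDV, ESV, LVM or EF) measured by R readers on N
cases, with F_i(k) reader i's value on case k and F_C(k) the consensus
value:

  E_i(F) = sqrt( sum_{j != i} sum_k (F_i(k) - F_j(k))^2 / (N (R-1)) )
  E_C(F) = sqrt( sum_j sum_k (F_C(k) - F_j(k))^2 / (N R) )

E_C smaller than every E_i indicates the consensus agrees with the readers
better than any individual reader does.  Bland-Altman statistics per
reader use the differences from the consensus: bias is their mean,
precision their sample SD (N-1 denominator), and the limits of agreement
bias +/- 1.96 SD.  The per-case consensus standard error is the RMS reader
deviation from the consensus divided by sqrt(R).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .volumetrics import LVFunction

INDEX_NAMES = ("EDV", "ESV", "LVM", "EF")
INDEX_UNITS = {"EDV": "ml", "ESV": "ml", "LVM": "g", "EF": "%"}


class AgreementError(ValueError):
    pass


@dataclass
class FunctionMatrix:
    """R x N grid of one functional index, plus an optional consensus row."""

    name: str
    readers: list
    cases: list
    values: np.ndarray
    consensus: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        R, N = len(self.readers), len(self.cases)
        if self.values.shape != (R, N):
            raise AgreementError(
                f"values shape {self.values.shape} != ({R}, {N})"
            )
        if R < 2 or N < 1:
            raise AgreementError("need >= 2 readers and >= 1 case")
        if not np.isfinite(self.values).all():
            raise AgreementError("missing cells are not allowed")
        if self.consensus is not None:
            self.consensus = np.asarray(self.consensus, dtype=float)
            if self.consensus.shape != (N,) or not np.isfinite(self.consensus).all():
                raise AgreementError("consensus row must be complete")

    @property
    def n_readers(self) -> int:
        return len(self.readers)

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def reader_index(self, reader: Union[int, str]) -> int:
        if isinstance(reader, str):
            return self.readers.index(reader)
        return int(reader)

    def _require_consensus(self) -> np.ndarray:
        if self.consensus is None:
            raise AgreementError(f"{self.name}: no consensus row")
        return self.consensus


def reader_rmse(m: FunctionMatrix, reader: Union[int, str]) -> float:
    """RMSE of reader i against all other readers over all cases."""
    i = m.reader_index(reader)
    diffs = m.values[i][None, :] - np.delete(m.values, i, axis=0)
    return float(np.sqrt(np.sum(diffs ** 2) / (m.n_cases * (m.n_readers - 1))))


def all_reader_rmse(m: FunctionMatrix) -> np.ndarray:
    return np.array([reader_rmse(m, i) for i in range(m.n_readers)])


def consensus_rmse(m: FunctionMatrix) -> float:
    """RMSE of the consensus against all readers over all cases."""
    consensus = m._require_consensus()
    diffs = consensus[None, :] - m.values
    return float(np.sqrt(np.sum(diffs ** 2) / (m.n_cases * m.n_readers)))


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    precision: float
    lower_limit: float
    upper_limit: float


def bland_altman(m: FunctionMatrix, reader: Union[int, str]) -> BlandAltman:
    """Bias, precision and 95% limits of agreement vs the consensus."""
    consensus = m._require_consensus()
    if m.n_cases < 2:
        raise AgreementError("precision needs at least two cases")
    i = m.reader_index(reader)
    d = m.values[i] - consensus
    bias = float(np.mean(d))
    precision = float(np.std(d, ddof=1))
    return BlandAltman(
        bias=bias,
        precision=precision,
        lower_limit=bias - 1.96 * precision,
        upper_limit=bias + 1.96 * precision,
    )


def consensus_se(m: FunctionMatrix, case: Union[int, str]) -> float:
    """Standard error of the consensus value on one case.

    RMS deviation of the readers from the consensus, divided by sqrt(R).
    """
    consensus = m._require_consensus()
    k = m.cases.index(case) if isinstance(case, str) else int(case)
    dev = m.values[:, k] - consensus[k]
    rms = np.sqrt(np.sum(dev ** 2) / m.n_readers)
    return float(rms / np.sqrt(m.n_readers))


def consensus_se_all(m: FunctionMatrix) -> np.ndarray:
    return np.array([consensus_se(m, k) for k in range(m.n_cases)])


@dataclass
class AgreementReport:
    """All agreement statistics for one functional index."""

    name: str
    readers: list
    cases: list
    e_i: np.ndarray
    e_c: float
    bias: np.ndarray
    precision: np.ndarray
    lower_limit: np.ndarray
    upper_limit: np.ndarray
    per_case_consensus: np.ndarray
    per_case_se: np.ndarray
    consensus_is_best: bool

    def reader_table(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "reader": self.readers,
            "E_i": self.e_i,
            "bias": self.bias,
            "precision": self.precision,
            "lower_limit": self.lower_limit,
            "upper_limit": self.upper_limit,
        })
        consensus_row = pd.DataFrame({
            "reader": ["consensus"], "E_i": [self.e_c],
            "bias": [0.0], "precision": [np.nan],
            "lower_limit": [np.nan], "upper_limit": [np.nan],
        })
        return pd.concat([df, consensus_row], ignore_index=True)

    def case_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "case": self.cases,
            f"{self.name}_consensus": self.per_case_consensus,
            f"{self.name}_se": self.per_case_se,
        })


def build_function_matrices(
    functions: Iterable[LVFunction],
    consensus_source: str = "consensus",
) -> dict[str, FunctionMatrix]:
    """Arrange per-case, per-source LVFunction values into R x N matrices.

    Sources other than ``consensus_source`` are readers; every reader must
    cover every case (the agreement formulas assume a complete grid).
    """
    by_source_case: dict[tuple[str, str], LVFunction] = {}
    for f in functions:
        by_source_case[(f.source_id, f.case_id)] = f
    sources = sorted({s for s, _ in by_source_case})
    cases = sorted({c for _, c in by_source_case})
    readers = [s for s in sources if s != consensus_source]
    if len(readers) < 2:
        raise AgreementError("need at least two reader sources")
    attr = {"EDV": "edv_ml", "ESV": "esv_ml", "LVM": "lvm_g", "EF": "ef_pct"}
    matrices = {}
    for name in INDEX_NAMES:
        values = np.empty((len(readers), len(cases)))
        for i, r in enumerate(readers):
            for k, c in enumerate(cases):
                f = by_source_case.get((r, c))
                if f is None:
                    raise AgreementError(f"missing cell: reader {r}, case {c}")
                values[i, k] = getattr(f, attr[name])
        consensus = None
        if consensus_source in sources:
            consensus = np.empty(len(cases))
            for k, c in enumerate(cases):
                f = by_source_case.get((consensus_source, c))
                if f is None:
                    raise AgreementError(f"missing consensus for case {c}")
                consensus[k] = getattr(f, attr[name])
        matrices[name] = FunctionMatrix(
            name=name, readers=list(readers), cases=list(cases),
            values=values, consensus=consensus,
        )
    return matrices


def summarize_cohort(
    matrices: Mapping[str, FunctionMatrix],
) -> dict[str, AgreementReport]:
    """Full agreement report per functional index.

    Flags, per index, whether E_C < min_i E_i (the consensus agreeing with
    the readers better than any individual reader does).
    """
    reports = {}
    for name, m in matrices.items():
        e_i = all_reader_rmse(m)
        e_c = consensus_rmse(m)
        ba = [bland_altman(m, i) for i in range(m.n_readers)]
        reports[name] = AgreementReport(
            name=name,
            readers=list(m.readers),
            cases=list(m.cases),
            e_i=e_i,
            e_c=e_c,
            bias=np.array([b.bias for b in ba]),
            precision=np.array([b.precision for b in ba]),
            lower_limit=np.array([b.lower_limit for b in ba]),
            upper_limit=np.array([b.upper_limit for b in ba]),
            per_case_consensus=np.asarray(m.consensus, dtype=float),
            per_case_se=consensus_se_all(m),
            consensus_is_best=bool(e_c < e_i.min()),
        )
    return reports
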