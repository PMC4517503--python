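"""End-to-end orchestration: cohort -> consensus -> function -> agreement.

Library counterpart of the command-line interface; also the entry point
used by the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .agreement_stats import build_function_matrices, summarize_cohort
from .staple import StapleParams, fuse_contour_sets
from .synthetic_data import CohortConfig, CohortResult, simulate_cohort
from .volumetrics import LVFunction, compute_lv_function


@dataclass
class CohortAnalysis:
    """Everything the full pipeline computes for one cohort."""

    cohort: CohortResult
    consensus_sets: dict
    fusion_outputs: dict
    functions: list
    matrices: dict
    reports: dict
    diagnostics: pd.DataFrame
    skipped: list = field(default_factory=list)

    def functions_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "case_id": f.case_id, "source_id": f.source_id,
            "EDV_ml": f.edv_ml, "ESV_ml": f.esv_ml,
            "LVM_g": f.lvm_g, "EF_pct": f.ef_pct,
        } for f in self.functions])


def analyze_case_sets(
    reader_sets_by_case: dict,
    staple_params: Optional[StapleParams] = None,
    factor: int = 4,
    min_readers: int = 4,
    consensus_sets: Optional[dict] = None,
) -> tuple[dict, dict, pd.DataFrame, list]:
    """Fuse every case (unless consensus supplied) and collect diagnostics."""
    fusion_outputs = {}
    out_consensus = {}
    diag_frames = []
    skipped = []
    for case_id, per_reader in reader_sets_by_case.items():
        if consensus_sets is not None and case_id in consensus_sets:
            out_consensus[case_id] = consensus_sets[case_id]
            continue
        fused = fuse_contour_sets(list(per_reader.values()),
                                  params=staple_params, factor=factor,
                                  min_readers=min_readers)
        fusion_outputs[case_id] = fused
        out_consensus[case_id] = fused.consensus
        if len(fused.diagnostics):
            diag_frames.append(fused.diagnostics)
        skipped.extend((case_id, *key) for key in fused.skipped)
    diagnostics = (pd.concat(diag_frames, ignore_index=True)
                   if diag_frames else pd.DataFrame())
    return out_consensus, fusion_outputs, diagnostics, skipped


def run_cohort_analysis(
    config: Optional[CohortConfig] = None,
    cohort: Optional[CohortResult] = None,
    staple_params: Optional[StapleParams] = None,
    factor: int = 4,
    min_readers: int = 4,
    backend: str = "polygon",
) -> CohortAnalysis:
    """Simulate (or accept) a cohort and run it through the full analysis.

    Per case: STAPLE fusion of the readers' slices under the >= min_readers
    rule; LV function for every reader and for the consensus; then the
    agreement statistics across the cohort.
    """
    if cohort is None:
        cohort = simulate_cohort(config or CohortConfig())
    consensus_sets, fusion_outputs, diagnostics, skipped = analyze_case_sets(
        cohort.reader_sets, staple_params=staple_params,
        factor=factor, min_readers=min_readers,
    )
    functions: list[LVFunction] = []
    for case_id, per_reader in cohort.reader_sets.items():
        for rs in per_reader.values():
            functions.append(compute_lv_function(rs, backend=backend, factor=factor))
        functions.append(compute_lv_function(consensus_sets[case_id],
                                             backend=backend, factor=factor))
    matrices = build_function_matrices(functions)
    reports = summarize_cohort(matrices)
    return CohortAnalysis(
        cohort=cohort, consensus_sets=consensus_sets,
        fusion_outputs=fusion_outputs, functions=functions,
        matrices=matrices, reports=reports,
        diagnostics=diagnostics, skipped=skipped,
    )
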