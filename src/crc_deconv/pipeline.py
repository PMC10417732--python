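"""End-to-end orchestration: simulate a draw, detect, profile, classify.

The molecular workup mirrors the assay's workflow: every cell on the slide
is screened by immunofluorescence, and only the detected candidates proceed
to single-cell sequencing and targeted proteomics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cnv, if_detection, imc, synthetic_data
from .classify import CellEvidence, DrawSummary, classify_cells, summarize_draw
from .config import SimulationConfig


@dataclass
class DrawResult:
    draw_id: str
    cells: pd.DataFrame
    candidates: pd.DataFrame
    clonality: pd.DataFrame | None
    marker_calls: pd.DataFrame | None
    classifications: pd.DataFrame
    summary: DrawSummary
    segment_sets: list = field(default_factory=list)


def clonal_status_from_result(result: cnv.ClonalityResult) -> str:
    if result.clonal_group:
        return "clonal"
    if not result.is_altered:
        return "non_altered"
    return "unknown"


def build_evidence(
    candidates: pd.DataFrame,
    clonal_status: dict[str, str] | None = None,
    marker_calls: pd.DataFrame | None = None,
) -> list[CellEvidence]:
    """Fuse detection output with optional genomic/proteomic evidence."""
    evidence = []
    for row in candidates.itertuples():
        cid = row.cell_id
        tissue = endo = None
        if marker_calls is not None and cid in marker_calls.index:
            tissue = bool(marker_calls.loc[cid, "tissue_marker_positive"])
            endo = bool(marker_calls.loc[cid, "endothelial_positive"])
        evidence.append(
            CellEvidence(
                cell_id=cid,
                cd45_positive=False,  # candidates passed the CD45 ceiling
                ck_sdom=float(row.ck_sdom),
                vim_call=bool(row.vim_call),
                eccentricity=float(row.eccentricity),
                clonal_status=(clonal_status or {}).get(cid, "unknown"),
                tissue_marker_positive=tissue,
                endothelial_positive=endo,
            )
        )
    return evidence


def run_draw(
    config: SimulationConfig,
    draw_id: str = "D1",
    timepoint_weeks: float = 0.0,
    disease_status: str = "unknown",
    bins: pd.DataFrame | None = None,
    alpha: float = 0.01,
    n_perm: int = 200,
    run_cnv: bool = True,
    run_imc: bool = True,
    cancer_type: str = "prostate",
    panel: pd.DataFrame | None = None,
) -> DrawResult:
    """Simulate one blood draw and push it through the full pipeline.

    Returns the raw cell table, the detected candidates, per-cell clonality
    and marker calls for the characterized subset, classifications and the
    draw summary.
    """
    if bins is None and run_cnv:
        bins = cnv.make_bins(cnv.default_genome(), config.n_bins, seed=config.seed)
    cells, truth = synthetic_data.generate_frame(config, frame_id=draw_id)
    candidates = if_detection.detect_candidates(cells)
    cand_ids = list(candidates["cell_id"])

    clonal_status: dict[str, str] = {}
    clonality_df = None
    segment_sets: list[cnv.SegmentSet] = []
    if run_cnv and cand_ids:
        profiles = synthetic_data.profiles_for_labels(truth.loc[cand_ids], bins, config)
        counts = synthetic_data.simulate_read_counts(profiles, bins, config)
        ratios = cnv.normalize_matrix(counts, bins)
        seed_rng = config.child_rngs("cbs")["cbs"]
        seeds = seed_rng.integers(0, 2**31 - 1, size=len(cand_ids))
        for cid, seed in zip(ratios.index, seeds):
            segset = cnv.segment_cbs(
                ratios.loc[cid].to_numpy(),
                bins,
                cell_id=str(cid),
                alpha=alpha,
                n_perm=n_perm,
                seed=int(seed),
            )
            segment_sets.append(cnv.call_states(segset))
        results = cnv.detect_clonality(segment_sets)
        clonality_df = cnv.clonality_table(results)
        clonal_status = {r.cell_id: clonal_status_from_result(r) for r in results}

    marker_calls = None
    if run_imc and cand_ids:
        panel = synthetic_data.DEFAULT_PANEL if panel is None else panel
        ions, background, ref_ids = synthetic_data.simulate_imc(
            truth.loc[cand_ids], panel, config, cancer_type=cancer_type
        )
        corrected = imc.subtract_background(ions, background)
        z = imc.zscore_normalize(corrected, ref_ids)
        marker_calls = imc.call_markers(z)

    evidence = build_evidence(candidates, clonal_status, marker_calls)
    classifications = classify_cells(evidence)
    if len(classifications) == 0:
        classifications = pd.DataFrame(columns=["cell_id", "label"])
    summary = summarize_draw(
        classifications, draw_id, timepoint_weeks=timepoint_weeks, disease_status=disease_status
    )
    return DrawResult(
        draw_id=draw_id,
        cells=cells,
        candidates=candidates,
        clonality=clonality_df,
        marker_calls=marker_calls,
        classifications=classifications,
        summary=summary,
        segment_sets=segment_sets,
    )


def run_longitudinal(
    base_config: SimulationConfig,
    draws: list[dict] | None = None,
    **run_kwargs,
) -> tuple[list[DrawResult], pd.DataFrame]:
    """Run a multi-draw scenario (defaults to the four-draw index patient)."""
    from .classify import longitudinal_table

    if draws is None:
        draws = synthetic_data.index_patient_draws()
    results = []
    for i, meta in enumerate(draws):
        cfg = base_config.with_(
            seed=base_config.seed + i, composition=meta["composition"]
        )
        results.append(
            run_draw(
                cfg,
                draw_id=meta["draw_id"],
                timepoint_weeks=meta["timepoint_weeks"],
                disease_status=meta["disease_status"],
                **run_kwargs,
            )
        )
    table = longitudinal_table([r.summary for r in results])
    return results, table
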