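"""Rare-cell taxonomy from fused immunofluorescence, genomic and proteomic evidence.

The taxonomy: EPI.CTC (clonal copy-number profile, vimentin-negative),
pEMT.CTC (clonal, vimentin-positive), CEC (copy-number neutral,
CD31-positive, elongated), WBC (CD45-positive), or unclassified when the
evidence cannot separate them — CK/Vim immunofluorescence alone cannot.
Genomic evidence outranks proteomic evidence on conflict, since clonal
copy-number alterations define tumor lineage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LABELS = ("EPI.CTC", "pEMT.CTC", "CEC", "WBC", "unclassified")
RARE_LABELS = ("EPI.CTC", "pEMT.CTC", "CEC")

DEFAULT_ELONGATION_CUTOFF = 0.8


@dataclass(frozen=True)
class CellEvidence:
    """Evidence bundle for one candidate cell.

    ``clonal_status`` is ``"clonal"``, ``"non_altered"`` or ``"unknown"``
    (no genomic data, or altered without clonal support);
    ``tissue_marker_positive``/``endothelial_positive`` are None when the
    cell has no proteomic data. Immunofluorescence fields are mandatory.
    """

    cell_id: str
    cd45_positive: bool
    ck_sdom: float
    vim_call: bool
    eccentricity: float
    clonal_status: str = "unknown"
    tissue_marker_positive: bool | None = None
    endothelial_positive: bool | None = None


@dataclass(frozen=True)
class CellClassification:
    cell_id: str
    label: str
    confidence_tier: str  # genomic+proteomic | genomic_only | proteomic_only | morphology_only
    conflict: bool  # clonal genome with endothelial proteome
    evidence: CellEvidence


def _confidence_tier(ev: CellEvidence) -> str:
    genomic = ev.clonal_status != "unknown"
    proteomic = ev.tissue_marker_positive is not None or ev.endothelial_positive is not None
    if genomic and proteomic:
        return "genomic+proteomic"
    if genomic:
        return "genomic_only"
    if proteomic:
        return "proteomic_only"
    return "morphology_only"


def classify_cell(
    ev: CellEvidence, elongation_cutoff: float = DEFAULT_ELONGATION_CUTOFF
) -> CellClassification:
    """Assign a taxonomy label by a fixed decision ladder (first match wins).

    1. CD45+  ->  WBC
    2. clonal and Vim-  ->  EPI.CTC
    3. clonal and Vim+  ->  pEMT.CTC
    4. tissue-marker+ and not endothelial+  ->  EPI.CTC / pEMT.CTC by Vim
    5. (non-altered or endothelial+) and Vim+ and elongated  ->  CEC
    6. endothelial+ alone  ->  CEC
    else unclassified.

    A clonal genome combined with an endothelial proteome is contradictory;
    the cell is classified by its genomics (CTC) and flagged.
    """
    tier = _confidence_tier(ev)
    endo = bool(ev.endothelial_positive)
    tissue = bool(ev.tissue_marker_positive)
    conflict = ev.clonal_status == "clonal" and endo

    if ev.cd45_positive:
        label = "WBC"
    elif ev.clonal_status == "clonal":
        label = "pEMT.CTC" if ev.vim_call else "EPI.CTC"
    elif tissue and not endo:
        label = "pEMT.CTC" if ev.vim_call else "EPI.CTC"
    elif (
        (ev.clonal_status == "non_altered" or endo)
        and ev.vim_call
        and ev.eccentricity >= elongation_cutoff
    ):
        label = "CEC"
    elif endo:
        label = "CEC"
    else:
        label = "unclassified"
    return CellClassification(ev.cell_id, label, tier, conflict, ev)


def classify_cells(
    evidence: list[CellEvidence], elongation_cutoff: float = DEFAULT_ELONGATION_CUTOFF
) -> pd.DataFrame:
    """Classify a cohort; returns a tidy table with evidence columns."""
    rows = []
    for ev in evidence:
        c = classify_cell(ev, elongation_cutoff=elongation_cutoff)
        rows.append(
            {
                "cell_id": ev.cell_id,
                "label": c.label,
                "confidence_tier": c.confidence_tier,
                "conflict": c.conflict,
                "cd45_positive": ev.cd45_positive,
                "ck_sdom": ev.ck_sdom,
                "vim_call": ev.vim_call,
                "eccentricity": ev.eccentricity,
                "clonal_status": ev.clonal_status,
                "tissue_marker_positive": ev.tissue_marker_positive,
                "endothelial_positive": ev.endothelial_positive,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DrawSummary:
    """Per-blood-draw composition of classified rare cells."""

    draw_id: str
    timepoint_weeks: float
    disease_status: str  # AD | SD | unknown
    counts: dict[str, int]
    fractions: dict[str, float]
    n_classified: int
    n_unclassified: int
    fractions_defined: bool

    def as_row(self) -> dict:
        row = {
            "draw_id": self.draw_id,
            "timepoint_weeks": self.timepoint_weeks,
            "disease_status": self.disease_status,
            "n_classified": self.n_classified,
            "n_unclassified": self.n_unclassified,
        }
        for label in RARE_LABELS:
            row[f"n_{label}"] = self.counts.get(label, 0)
            row[f"frac_{label}"] = self.fractions.get(label, np.nan)
        return row


def summarize_draw(
    classifications: pd.DataFrame,
    draw_id: str,
    timepoint_weeks: float = np.nan,
    disease_status: str = "unknown",
) -> DrawSummary:
    """Counts and fractions per rare-cell label for one draw.

    Fractions are over classified rare cells (WBC and unclassified rows are
    excluded from the denominator) and sum to 1 when any cell classified;
    with zero classified cells the fractions are undefined and flagged.
    """
    rare = classifications[classifications["label"].isin(RARE_LABELS)]
    counts = {label: int((rare["label"] == label).sum()) for label in RARE_LABELS}
    total = sum(counts.values())
    defined = total > 0
    fractions = {
        label: (counts[label] / total if defined else np.nan) for label in RARE_LABELS
    }
    n_unclassified = int((classifications["label"] == "unclassified").sum())
    return DrawSummary(
        draw_id=draw_id,
        timepoint_weeks=timepoint_weeks,
        disease_status=disease_status,
        counts=counts,
        fractions=fractions,
        n_classified=total,
        n_unclassified=n_unclassified,
        fractions_defined=defined,
    )


def longitudinal_table(summaries: list[DrawSummary]) -> pd.DataFrame:
    """Tidy per-draw time series, sorted by timepoint (stable for ties)."""
    df = pd.DataFrame([s.as_row() for s in summaries])
    return df.sort_values("timepoint_weeks", kind="stable").reset_index(drop=True)
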