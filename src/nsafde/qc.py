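"""Technical-replicate QC and control-proteome annotation.

Two questions are answered here.  First, how reproducible are the triplicate
runs: the coefficient of variation (CV) of the per-run protein totals
measures intra-assay variability.  Second, is the observed differential
expression meaningful relative to that variability: if the fraction of
proteins called differentially expressed between two conditions does not
exceed the replicate CV, the difference between the conditions is judged to
be within technical noise.  A separate control proteome (e.g. a pure
leukocyte culture) can then be used to ask whether the called proteins are
plausibly contaminants: a protein absent or strongly underexpressed in the
control cannot have been contributed by the contaminating cell type.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SpectralCountMatrix
from .model import Call, DEPCall, call_expression
from .nsaf import nsaf_ratio
from .tiers import DEFAULT_THRESHOLDS, Tier, TierThresholds, classify_abundance

__all__ = [
    "Verdict",
    "ControlStatus",
    "QCSummary",
    "ControlAnnotations",
    "cv_percent",
    "run_protein_totals",
    "group_cv_percent",
    "interference_assessment",
    "qc_summary",
    "annotate_with_control",
]


class Verdict(str, enum.Enum):
    WITHIN = "within_technical_variability"
    EXCEEDS = "exceeds_technical_variability"


class ControlStatus(str, enum.Enum):
    ABSENT = "absent_in_control"
    UNDEREXPRESSED = "underexpressed_in_control"
    OVEREXPRESSED = "overexpressed_in_control"
    NOT_SIGNIFICANT = "not_significant"


def cv_percent(values: Sequence[float], ddof: int = 1) -> float:
    """Coefficient of variation, in percent.

    Uses the sample (n-1) standard deviation by default; with only three
    replicates the ddof choice is material, so it is exposed.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100.0 * x.std(ddof=ddof) / mean)


def run_protein_totals(matrix: SpectralCountMatrix) -> dict[str, int]:
    """Number of proteins detected (count > 0) in each run."""
    return {run: int((matrix.counts[run] > 0).sum()) for run in matrix.run_ids}


def group_cv_percent(matrix: SpectralCountMatrix, ddof: int = 1) -> dict[str, float]:
    """CV of the per-run protein totals within each group."""
    totals = run_protein_totals(matrix)
    out: dict[str, float] = {}
    for group in matrix.groups:
        runs = matrix.runs_for_group(group)
        if len(runs) >= 2:
            out[group] = cv_percent([totals[r] for r in runs], ddof=ddof)
    return out


def interference_assessment(
    dep_fraction_percent: float, cvs: Mapping[str, float]
) -> Verdict:
    """Compare the DEP fraction against the replicate CVs.

    The difference between conditions is judged within technical
    variability iff the DEP percentage does not exceed the largest group CV
    (inclusive at equality).
    """
    if not cvs:
        raise ValueError("no group CVs supplied")
    return Verdict.WITHIN if dep_fraction_percent <= max(cvs.values()) else Verdict.EXCEEDS


@dataclass
class QCSummary:
    """Per-run totals, per-group CVs, and the interference verdict.

    ``verdict`` is None when no group has enough replicates for a CV (e.g.
    a means-only table analyzed as single pseudo-replicates)."""

    per_run_totals: dict[str, int]
    per_group_cv_percent: dict[str, float]
    dep_fraction_percent: float
    verdict: Verdict | None

    def to_frame(self, design: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for run, total in self.per_run_totals.items():
            rows.append(
                {
                    "run_id": run,
                    "group": design.loc[run, "group"],
                    "replicate": design.loc[run, "replicate"],
                    "n_proteins": total,
                }
            )
        return pd.DataFrame(rows)


def qc_summary(
    matrix: SpectralCountMatrix, dep_fraction_percent: float, ddof: int = 1
) -> QCSummary:
    """Assemble the QC summary for one matrix and a DEP fraction."""
    cvs = group_cv_percent(matrix, ddof=ddof)
    return QCSummary(
        per_run_totals=run_protein_totals(matrix),
        per_group_cv_percent=cvs,
        dep_fraction_percent=dep_fraction_percent,
        verdict=interference_assessment(dep_fraction_percent, cvs) if cvs else None,
    )


class ControlAnnotations:
    """Differential-expression calls annotated against a control proteome.

    ``annotations`` has one row per input call: the control group's mean
    spectral count and tier, the NSAF ratio control/reference, and a status
    from the same tiered classifier (governing tier = max of reference and
    control tiers).  ``n_shared_all_three`` counts the calls whose protein
    was detected in the reference group, the comparison group, *and* the
    control.
    """

    def __init__(self, annotations: pd.DataFrame, n_shared_all_three: int) -> None:
        self.annotations = annotations
        self.n_shared_all_three = n_shared_all_three

    def status_counts(self) -> dict[str, int]:
        return self.annotations["status"].value_counts().to_dict()

    def to_tsv(self, path: str | Path) -> None:
        out = self.annotations.copy()
        out["control_mean_sc"] = out["control_mean_sc"].round(1)
        out["ratio_control_over_ref"] = out["ratio_control_over_ref"].map(
            lambda r: "inf" if math.isinf(r) else f"{r:.2f}"
        )
        out.to_csv(path, sep="\t", index=True)


def annotate_with_control(
    dep_calls: Iterable[DEPCall],
    control_matrix: SpectralCountMatrix,
    thresholds: TierThresholds = DEFAULT_THRESHOLDS,
    control_group: str | None = None,
    nsaf_ratios: Mapping[str, float] | None = None,
    reference_matrix: SpectralCountMatrix | None = None,
    reference_group: str | None = None,
) -> ControlAnnotations:
    """Annotate two-group DEP calls with a control proteome.

    Parameters
    ----------
    dep_calls : iterable of DEPCall
        Calls from a reference-vs-comparison fit (typically only the DEPs).
    control_matrix : SpectralCountMatrix
        Counts for the control proteome; proteins missing from it are
        treated as undetected in the control.
    control_group : str, optional
        Which design group of ``control_matrix`` is the control; defaults to
        its only group.
    nsaf_ratios : mapping accession -> float, optional
        Externally supplied control/reference NSAF ratios, overriding the
        ratio computed from the matrices' NSAF (same escape hatch as in
        :class:`~nsafde.model.DifferentialExpression`).
    reference_matrix, reference_group : optional
        Where to compute the reference-group NSAF from.  Required for any
        protein not covered by ``nsaf_ratios``, because a call object only
        carries its group mean counts, not the run-level NSAF.
    """
    from .nsaf import group_mean_nsaf

    if control_group is None:
        groups = control_matrix.groups
        if len(groups) != 1:
            raise ValueError("control_group must be named when the control "
                             f"matrix has {len(groups)} groups")
        control_group = groups[0]
    override = dict(nsaf_ratios) if nsaf_ratios else {}

    control_sc = control_matrix.group_mean_counts(control_group)
    control_nsaf = pd.Series(
        group_mean_nsaf(control_matrix, control_group), index=control_matrix.accessions
    )
    ref_nsaf: pd.Series | None = None
    if reference_matrix is not None:
        if reference_group is None:
            raise ValueError("reference_group must accompany reference_matrix")
        ref_nsaf = pd.Series(
            group_mean_nsaf(reference_matrix, reference_group),
            index=reference_matrix.accessions,
        )

    rows = []
    n_shared = 0
    for call in dep_calls:
        acc = call.accession
        c_sc = float(control_sc.get(acc, 0.0))
        c_tier = classify_abundance(c_sc)
        if call.mean_sc_ref > 0 and call.mean_sc_cmp > 0 and c_sc > 0:
            n_shared += 1
        if c_sc == 0:
            status = ControlStatus.ABSENT
            ratio = 0.0
            p = math.nan
        else:
            if acc in override:
                ratio = override[acc]
            elif ref_nsaf is not None:
                ratio = nsaf_ratio(float(ref_nsaf.get(acc, 0.0)), float(control_nsaf[acc]))
            else:
                raise ValueError(
                    f"no NSAF ratio available for {acc}: supply nsaf_ratios "
                    "or a reference matrix"
                )
            # zero-variance means-only comparison: means differ -> p = 0
            p = 1.0 if c_sc == call.mean_sc_ref else 0.0
            shadow = call_expression(
                call.mean_sc_ref, c_sc, ratio, p, thresholds, accession=acc
            )
            status = {
                Call.OVEREXPRESSED: ControlStatus.OVEREXPRESSED,
                Call.UNDEREXPRESSED: ControlStatus.UNDEREXPRESSED,
                Call.NOT_SIGNIFICANT: ControlStatus.NOT_SIGNIFICANT,
            }[shadow.call]
        rows.append(
            {
                "accession": acc,
                "mean_sc_ref": call.mean_sc_ref,
                "tier_ref": call.tier_ref.label,
                "mean_sc_cmp": call.mean_sc_cmp,
                "tier_cmp": call.tier_cmp.label,
                "control_mean_sc": c_sc,
                "control_tier": c_tier.label,
                "ratio_control_over_ref": ratio,
                "status": status.value,
            }
        )
    frame = pd.DataFrame(rows).set_index("accession") if rows else pd.DataFrame(
        columns=["mean_sc_ref", "tier_ref", "mean_sc_cmp", "tier_cmp",
                 "control_mean_sc", "control_tier", "ratio_control_over_ref", "status"]
    )
    return ControlAnnotations(frame, n_shared)
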