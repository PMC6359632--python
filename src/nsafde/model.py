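"""Abundance-tiered differential expression on NSAF-quantified spectral counts.

The model compares a *reference* group against a *comparison* group of
technical-replicate LC-MS/MS runs.  For each protein it computes the mean
spectral count per group, the NSAF ratio (comparison / reference), and a
two-sample t-test p-value on the per-run NSAF values; the protein's
abundance tier (the higher of its two group tiers) then selects which
p-value ceiling and ratio cutoffs decide the call.

Usage follows the model/results convention::

    model = DifferentialExpression(matrix, reference="group1", comparison="group3")
    res = model.fit()
    print(res.summary())
    res.to_tsv("dep_report.tsv")

Proteins detected in only one group are called unique to that group without
a test; proteins absent from both are not part of the comparison.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import SpectralCountMatrix, read_count_matrix
from .nsaf import compute_nsaf, nsaf_ratio, ttest_independent
from .tiers import DEFAULT_THRESHOLDS, Tier, TierThresholds, classify_abundance, governing_tier

__all__ = ["Call", "DEPCall", "call_expression", "DifferentialExpression", "DEResults"]


class Call(str, enum.Enum):
    OVEREXPRESSED = "overexpressed"
    UNDEREXPRESSED = "underexpressed"
    UNIQUE_TO_CMP = "unique_to_cmp"
    UNIQUE_TO_REF = "unique_to_ref"
    NOT_SIGNIFICANT = "not_significant"
    ABSENT_IN_BOTH = "absent_in_both"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Calls that count as differential expression.
DEP_CALLS = frozenset({Call.OVEREXPRESSED, Call.UNDEREXPRESSED, Call.UNIQUE_TO_CMP, Call.UNIQUE_TO_REF})


@dataclass(frozen=True)
class DEPCall:
    """Per-protein outcome of a two-group comparison."""

    accession: str
    mean_sc_ref: float
    mean_sc_cmp: float
    tier_ref: Tier
    tier_cmp: Tier
    governing_tier: Tier
    nsaf_ratio: float
    p_value: float
    call: Call


def call_expression(
    mean_sc_ref: float,
    mean_sc_cmp: float,
    ratio: float,
    p_value: float,
    thresholds: TierThresholds = DEFAULT_THRESHOLDS,
    accession: str = "",
) -> DEPCall:
    """Classify one protein given its group means, NSAF ratio and p-value.

    Presence/absence is resolved first: a zero mean in exactly one group
    yields a unique call regardless of the test, and zero in both yields
    ``absent_in_both``.  Otherwise the governing tier's cutoffs apply:
    overexpressed iff p <= p_max and ratio >= oe_ratio_min; underexpressed
    iff p <= p_max and ratio <= ue_ratio_max; else not significant.  All
    comparisons are inclusive at the boundary.
    """
    tier_ref = classify_abundance(mean_sc_ref)
    tier_cmp = classify_abundance(mean_sc_cmp)

    if tier_ref is Tier.ABSENT and tier_cmp is Tier.ABSENT:
        return DEPCall(accession, mean_sc_ref, mean_sc_cmp, tier_ref, tier_cmp,
                       Tier.ABSENT, math.nan, math.nan, Call.ABSENT_IN_BOTH)
    if tier_ref is Tier.ABSENT:
        return DEPCall(accession, mean_sc_ref, mean_sc_cmp, tier_ref, tier_cmp,
                       tier_cmp, math.inf, math.nan, Call.UNIQUE_TO_CMP)
    if tier_cmp is Tier.ABSENT:
        return DEPCall(accession, mean_sc_ref, mean_sc_cmp, tier_ref, tier_cmp,
                       tier_ref, 0.0, math.nan, Call.UNIQUE_TO_REF)

    gov = governing_tier(tier_ref, tier_cmp)
    cut = thresholds[gov]
    if p_value <= cut.p_max and ratio >= cut.oe_ratio_min:
        call = Call.OVEREXPRESSED
    elif p_value <= cut.p_max and ratio <= cut.ue_ratio_max:
        call = Call.UNDEREXPRESSED
    else:
        call = Call.NOT_SIGNIFICANT
    return DEPCall(accession, mean_sc_ref, mean_sc_cmp, tier_ref, tier_cmp,
                   gov, ratio, p_value, call)


class DifferentialExpression:
    """Two-group NSAF differential expression model.

    Parameters
    ----------
    matrix : SpectralCountMatrix
        Counts, metadata, and run design.
    reference, comparison : str
        Group names from the design; the NSAF ratio is comparison/reference.
    thresholds : TierThresholds, optional
        Tier-specific cutoffs; defaults to the standard scheme.
    nsaf_ratios : mapping accession -> float, optional
        Externally supplied NSAF ratios (e.g. transcribed from a published
        report whose normalization denominators spanned the full proteome and
        cannot be recomputed from the tabulated counts alone).  Proteins not
        in the mapping fall back to ratios computed from the matrix.
    """

    def __init__(
        self,
        matrix: SpectralCountMatrix,
        reference: str,
        comparison: str,
        thresholds: TierThresholds = DEFAULT_THRESHOLDS,
        nsaf_ratios: Mapping[str, float] | None = None,
    ) -> None:
        if reference == comparison:
            raise ValueError("reference and comparison group must differ")
        self.matrix = matrix
        self.reference = reference
        self.comparison = comparison
        self.thresholds = thresholds
        self.nsaf_ratios = dict(nsaf_ratios) if nsaf_ratios else {}
        # raises InputError for unknown groups up front
        matrix.runs_for_group(reference)
        matrix.runs_for_group(comparison)

    @classmethod
    def from_files(
        cls,
        counts_path: str | Path,
        design_path: str | Path,
        reference: str,
        comparison: str,
        **kwargs,
    ) -> "DifferentialExpression":
        return cls(read_count_matrix(counts_path, design_path), reference, comparison, **kwargs)

    def fit(self) -> "DEResults":
        m = self.matrix
        lengths = m.lengths().to_numpy()
        runs_ref = m.runs_for_group(self.reference)
        runs_cmp = m.runs_for_group(self.comparison)
        nsaf_ref = np.column_stack(
            [compute_nsaf(m.counts[r].to_numpy(), lengths) for r in runs_ref]
        )
        nsaf_cmp = np.column_stack(
            [compute_nsaf(m.counts[r].to_numpy(), lengths) for r in runs_cmp]
        )
        sc_ref = m.counts[runs_ref].mean(axis=1).to_numpy()
        sc_cmp = m.counts[runs_cmp].mean(axis=1).to_numpy()
        mean_nsaf_ref = nsaf_ref.mean(axis=1)
        mean_nsaf_cmp = nsaf_cmp.mean(axis=1)

        calls: list[DEPCall] = []
        for i, acc in enumerate(m.accessions):
            if sc_ref[i] == 0 and sc_cmp[i] == 0:
                continue  # not identified in either compared group
            if acc in self.nsaf_ratios:
                ratio = self.nsaf_ratios[acc]
            else:
                ratio = nsaf_ratio(mean_nsaf_ref[i], mean_nsaf_cmp[i])
            p = ttest_independent(nsaf_ref[i], nsaf_cmp[i])
            dc = call_expression(sc_ref[i], sc_cmp[i], ratio, p, self.thresholds, accession=acc)
            calls.append(dc)
        return DEResults(self, calls)


class DEResults:
    """Fitted differential-expression results.

    Attributes
    ----------
    calls : pandas.DataFrame
        One row per protein present in either group, indexed by accession.
    """

    def __init__(self, model: DifferentialExpression, calls: list[DEPCall]) -> None:
        self.model = model
        self.reference = model.reference
        self.comparison = model.comparison
        self._calls = calls
        proteins = model.matrix.proteins
        self.calls = pd.DataFrame(
            {
                "gene": [proteins.loc[c.accession, "gene"] for c in calls],
                "description": [proteins.loc[c.accession, "description"] for c in calls],
                "mean_sc_ref": [c.mean_sc_ref for c in calls],
                "tier_ref": [c.tier_ref.label for c in calls],
                "mean_sc_cmp": [c.mean_sc_cmp for c in calls],
                "tier_cmp": [c.tier_cmp.label for c in calls],
                "governing_tier": [c.governing_tier.label for c in calls],
                "nsaf_ratio": [c.nsaf_ratio for c in calls],
                "p_value": [c.p_value for c in calls],
                "call": [c.call.value for c in calls],
            },
            index=pd.Index([c.accession for c in calls], name="accession"),
        )

    # -- headline counts -------------------------------------------------------

    @property
    def n_proteins_union(self) -> int:
        return len(self._calls)

    @property
    def n_overexpressed(self) -> int:
        return sum(c.call is Call.OVEREXPRESSED for c in self._calls)

    @property
    def n_underexpressed(self) -> int:
        return sum(c.call is Call.UNDEREXPRESSED for c in self._calls)

    @property
    def n_unique(self) -> int:
        return sum(c.call in (Call.UNIQUE_TO_CMP, Call.UNIQUE_TO_REF) for c in self._calls)

    @property
    def n_dep(self) -> int:
        return sum(c.call in DEP_CALLS for c in self._calls)

    @property
    def dep_fraction_percent(self) -> float:
        """DEPs as a percentage of all proteins identified in either group."""
        if self.n_proteins_union == 0:
            return 0.0
        return 100.0 * self.n_dep / self.n_proteins_union

    def dep_calls(self) -> pd.DataFrame:
        """Only the rows called differentially expressed."""
        return self.calls[self.calls["call"].isin({c.value for c in DEP_CALLS})]

    @property
    def call_records(self) -> list[DEPCall]:
        """All per-protein calls as :class:`DEPCall` records."""
        return list(self._calls)

    def dep_call_records(self) -> list[DEPCall]:
        """Only the differentially expressed calls, as records (the form
        :func:`~nsafde.qc.annotate_with_control` consumes)."""
        return [c for c in self._calls if c.call in DEP_CALLS]

    # -- reporting -------------------------------------------------------------

    def expression_label(self, call_value: str) -> str:
        return {
            Call.OVEREXPRESSED.value: "OE",
            Call.UNDEREXPRESSED.value: "UE",
            Call.UNIQUE_TO_REF.value: f"Unique to {self.reference}",
            Call.UNIQUE_TO_CMP.value: f"Unique to {self.comparison}",
            Call.NOT_SIGNIFICANT.value: "NS",
        }[call_value]

    def report(self) -> pd.DataFrame:
        """Human-readable report table (one row per protein).

        Spectral-count means are rounded to 1 decimal and ratios to 2, the
        precision conventional for published spectral-count tables; a unique
        protein's ratio prints as 0.00 or inf.
        """
        c = self.calls
        return pd.DataFrame(
            {
                "accession": c.index,
                "gene": c["gene"].to_numpy(),
                "description": c["description"].to_numpy(),
                "SC_ref": c["mean_sc_ref"].round(1).to_numpy(),
                "Abun_ref": c["tier_ref"].to_numpy(),
                "SC_cmp": c["mean_sc_cmp"].round(1).to_numpy(),
                "Abun_cmp": c["tier_cmp"].to_numpy(),
                "NSAF_ratio": [
                    "inf" if math.isinf(r) else f"{r:.2f}" for r in c["nsaf_ratio"]
                ],
                "p_value": c["p_value"].to_numpy(),
                "Expression": [self.expression_label(v) for v in c["call"]],
            }
        ).reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        self.report().to_csv(path, sep="\t", index=False)

    def summary_dict(self) -> dict:
        return {
            "reference": self.reference,
            "comparison": self.comparison,
            "n_proteins_union": self.n_proteins_union,
            "n_dep": self.n_dep,
            "n_oe": self.n_overexpressed,
            "n_ue": self.n_underexpressed,
            "n_unique": self.n_unique,
            "dep_fraction_percent": round(self.dep_fraction_percent, 2),
        }

    def summary(self) -> str:
        lines = [
            "NSAF differential expression",
            "=" * 44,
            f"reference group:        {self.reference}",
            f"comparison group:       {self.comparison}",
            f"proteins in comparison: {self.n_proteins_union}",
            f"differentially expressed: {self.n_dep} "
            f"({self.dep_fraction_percent:.2f}%)",
            f"  overexpressed:        {self.n_overexpressed}",
            f"  underexpressed:       {self.n_underexpressed}",
            f"  unique to one group:  {self.n_unique}",
            "=" * 44,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<DEResults {self.reference} vs {self.comparison}: "
                f"{self.n_dep} DEPs / {self.n_proteins_union} proteins>")
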