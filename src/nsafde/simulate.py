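"""Seeded spectral-count simulator with planted differential expression.

The generator emulates the study design the pipeline targets: two pooled
samples (reference and comparison), each injected as ``n_replicates``
technical LC-MS/MS replicates.  Because the replicates are technical —
repeat measurements of the same pooled protein extract — between-run
variation is pure counting noise: Poisson by default, negative binomial
(gamma-Poisson) when ``dispersion`` > 0.

Expected counts follow the physics of spectral counting: protein *i*
contributes spectra in proportion to its molar abundance ``a_i`` times its
length ``L_i`` (longer proteins produce more tryptic peptides).  This is
exactly the length bias NSAF divides out, so the simulator exercises the
normalization rather than assuming it away.  A planted fold change
``f_i`` multiplies the abundance of a DEP subset in the comparison group,
and each run's expected total is held at ``depth`` — as in real data, where
instrument time, not biology, fixes the number of spectra per run.  Note
the consequence, shared with real spectral counting: planting strong
one-sided fold changes deflates every other protein's *relative* abundance
in the comparison group.

Counts below ``detection_floor`` are zeroed — a crude stand-in for the
"at least two identified peptides" acceptance rule, which makes faint
proteins drop out of single runs the way they do in real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import SpectralCountMatrix
from .model import Call, DEPCall

__all__ = ["SimConfig", "SimTruth", "simulate_counts", "evaluate_recovery", "read_sim_config"]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    Defaults describe a desk-scale two-group triplicate experiment: 300
    proteins at 50,000 expected spectra per run, protein lengths log-normal
    around a 400-residue median (clipped to 50-5000 aa), and relative
    abundances log-normal with sdlog 1.6 — a ~3.5-decade dynamic range,
    matching the spread of spectral counts seen in deep shotgun runs of
    complex samples (means from below 1 to a few thousand).
    """

    n_proteins: int = 300
    n_dep: int = 0
    fold_changes: tuple[float, ...] = (10.0,)
    depth: float = 50_000.0
    n_replicates: int = 3
    dispersion: float = 0.0
    length_meanlog: float = float(np.log(400.0))
    length_sdlog: float = 0.5
    length_min: int = 50
    length_max: int = 5000
    abundance_meanlog: float = 0.0
    abundance_sdlog: float = 1.6
    detection_floor: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dep > self.n_proteins:
            raise ValueError("n_dep exceeds n_proteins")
        if self.n_proteins < 1 or self.depth <= 0 or self.n_replicates < 1:
            raise ValueError("n_proteins, depth and n_replicates must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if any(f <= 0 for f in self.fold_changes):
            raise ValueError("fold changes must be positive")
        if self.length_sdlog < 0 or self.abundance_sdlog < 0:
            raise ValueError("log-normal sdlog must be >= 0")
        if not 1 <= self.length_min <= self.length_max:
            raise ValueError("invalid length clip range")


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth: per-protein DEP flag and true fold change."""

    accessions: tuple[str, ...]
    is_dep: tuple[bool, ...]
    true_fold: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"is_dep": self.is_dep, "true_fold": self.true_fold},
            index=pd.Index(self.accessions, name="accession"),
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().reset_index().to_csv(path, sep="\t", index=False)


def _draw_counts(rng: np.random.Generator, lam: np.ndarray, dispersion: float) -> np.ndarray:
    """Poisson counts, or gamma-Poisson with Var = lam + dispersion * lam^2."""
    if dispersion == 0:
        return rng.poisson(lam).astype(float)
    shape = 1.0 / dispersion
    lam_mixed = rng.gamma(shape, lam * dispersion)
    return rng.poisson(lam_mixed).astype(float)


def simulate_counts(config: SimConfig) -> tuple[SpectralCountMatrix, SimTruth]:
    """Generate a two-group spectral-count matrix and its ground truth.

    Groups are named ``ref`` and ``cmp`` with runs ``ref_1..ref_k`` and
    ``cmp_1..cmp_k``.  Fold changes from ``config.fold_changes`` are planted
    cyclically across the DEP subset and apply to the comparison group.
    Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins

    lengths = np.exp(rng.normal(config.length_meanlog, config.length_sdlog, n))
    lengths = np.clip(np.round(lengths), config.length_min, config.length_max).astype(int)
    abundance = np.exp(rng.normal(config.abundance_meanlog, config.abundance_sdlog, n))

    dep_idx = rng.choice(n, size=config.n_dep, replace=False) if config.n_dep else np.array([], dtype=int)
    fold = np.ones(n)
    for k, i in enumerate(np.sort(dep_idx)):
        fold[i] = config.fold_changes[k % len(config.fold_changes)]

    w_ref = abundance * lengths
    w_cmp = abundance * fold * lengths
    lam_ref = config.depth * w_ref / w_ref.sum()
    lam_cmp = config.depth * w_cmp / w_cmp.sum()

    runs, columns = [], {}
    design_rows = []
    for group, lam in (("ref", lam_ref), ("cmp", lam_cmp)):
        for rep in range(1, config.n_replicates + 1):
            run_id = f"{group}_{rep}"
            x = _draw_counts(rng, lam, config.dispersion)
            x[x < config.detection_floor] = 0.0
            columns[run_id] = x
            design_rows.append({"run_id": run_id, "group": group, "replicate": rep})

    accessions = [f"SIM{i:05d}" for i in range(n)]
    proteins = pd.DataFrame(
        {
            "gene": [f"G{i}" for i in range(n)],
            "description": ["simulated protein"] * n,
            "length": lengths,
        },
        index=pd.Index(accessions, name="accession"),
    )
    counts = pd.DataFrame(columns, index=proteins.index)
    design = pd.DataFrame(design_rows).set_index("run_id")
    matrix = SpectralCountMatrix(proteins=proteins, counts=counts, design=design)
    truth = SimTruth(
        accessions=tuple(accessions),
        is_dep=tuple(fold != 1.0),
        true_fold=tuple(fold),
    )
    return matrix, truth


def evaluate_recovery(
    calls: Iterable[DEPCall], truth: SimTruth
) -> tuple[float, float, pd.DataFrame]:
    """Score classifier calls against planted truth.

    A planted DEP counts as recovered only when it is called in the
    direction of its true fold (overexpressed / unique-to-comparison for
    fold > 1, underexpressed / unique-to-reference for fold < 1).  Any other
    non-null call — a call on a non-DEP protein, or a DEP called the wrong
    way — is a false call.

    Returns
    -------
    sensitivity : recovered / n_dep (0.0 when nothing was planted)
    false_discovery_proportion : false calls / max(1, total calls)
    confusion : per-governing-tier counts of true/false calls and misses
    """
    truth_frame = truth.to_frame()
    up_calls = {Call.OVEREXPRESSED, Call.UNIQUE_TO_CMP}
    down_calls = {Call.UNDEREXPRESSED, Call.UNIQUE_TO_REF}

    n_dep = int(truth_frame["is_dep"].sum())
    recovered = 0
    false = 0
    total = 0
    rows: dict[str, dict[str, int]] = {}
    for call in calls:
        if call.accession not in truth_frame.index:
            raise ValueError(f"call for unknown accession {call.accession}")
        tier = call.governing_tier.label
        row = rows.setdefault(tier, {"true_calls": 0, "false_calls": 0, "missed": 0})
        if call.call not in up_calls and call.call not in down_calls:
            if truth_frame.loc[call.accession, "is_dep"]:
                row["missed"] += 1
            continue
        total += 1
        is_dep = bool(truth_frame.loc[call.accession, "is_dep"])
        f = float(truth_frame.loc[call.accession, "true_fold"])
        direction_ok = (f > 1 and call.call in up_calls) or (f < 1 and call.call in down_calls)
        if is_dep and direction_ok:
            recovered += 1
            row["true_calls"] += 1
        else:
            false += 1
            row["false_calls"] += 1
    sensitivity = recovered / n_dep if n_dep else 0.0
    fdp = false / max(1, total)
    confusion = pd.DataFrame(rows).T.rename_axis("governing_tier") if rows else pd.DataFrame(
        columns=["true_calls", "false_calls", "missed"]
    )
    return sensitivity, fdp, confusion


def read_sim_config(path: str | Path, seed: int | None = None) -> SimConfig:
    """Read a flat ``key = value`` config file into a :class:`SimConfig`.

    Lines starting with ``#`` are comments.  ``fold_changes`` is a
    comma-separated list.  A ``seed`` argument overrides any seed in the
    file.
    """
    fields = {f.name: f.type for f in SimConfig.__dataclass_fields__.values()}
    kwargs: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in fields:
            raise ValueError(f"unknown simulation parameter {key!r}")
        if key == "fold_changes":
            kwargs[key] = tuple(float(v) for v in value.split(","))
        elif key in ("n_proteins", "n_dep", "n_replicates", "seed", "length_min", "length_max"):
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    config = SimConfig(**kwargs)
    if seed is not None:
        config = replace(config, seed=seed)
    return config
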