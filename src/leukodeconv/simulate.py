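"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study design end to end: a signature matrix with
per-type marker-gene blocks (optionally overlapping, to mimic closely related
cell types), bulk mixtures built as m = B·f from Dirichlet-distributed
fractions with multiplicative lognormal noise (microarray-like,
scale-dependent error), matched pseudo-flow panels (percentages with
multiplicative Gaussian measurement noise), and a three-arm treatment cohort
(placebo / low dose / high dose) with injected per-signature effects plus age
and gender covariates that can be made deliberately confounded.

Every generator is fully deterministic under a fixed seed, and the seed is
recorded in the returned :class:`GroundTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io

__all__ = [
    "GroundTruth",
    "make_signature_matrix",
    "make_mixtures",
    "make_flow",
    "make_cohort",
    "identity_mapping",
    "write_preset",
]

#: CLARITY-subset arm sizes (placebo, low dose, high dose)
DEFAULT_ARM_SIZES = (57, 62, 70)

_TREATED_ARMS = {
    "low_vs_placebo": ("low_dose",),
    "high_vs_placebo": ("high_dose",),
    "combined_vs_placebo": ("low_dose", "high_dose"),
}


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    seed: int
    fractions: pd.DataFrame | None = None  # samples × cell types, rows on the simplex
    effects: dict = field(default_factory=dict)  # signature -> (contrast, delta)
    noise: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "noise": self.noise,
            "effects": {k: list(v) for k, v in self.effects.items()},
        }
        if self.fractions is not None:
            payload["fractions"] = {
                s: self.fractions.loc[s].round(10).to_dict() for s in self.fractions.index
            }
        Path(path).write_text(json.dumps(payload, indent=1))


def make_signature_matrix(
    n_genes: int,
    n_types: int,
    overlap: float = 0.0,
    seed: int = 0,
    marker_fold: float = 10.0,
    base_level: float = 50.0,
) -> pd.DataFrame:
    """Block-marker signature matrix (genes × cell types).

    Each cell type owns a block of high-expression marker genes on a noisy
    common background; ``overlap`` shifts adjacent blocks onto shared genes
    (0 = disjoint markers, 0.5 = half shared).  A marker gene carries one
    amplitude drawn per gene and shared across all cell types that use it —
    as for real transcriptionally related cell types, shared markers are
    similarly expressed, which is precisely what makes such types hard to
    separate.  The matrix has full column rank for overlap < 0.5.  The
    per-type marker genes are recorded in ``B.attrs['markers']``.
    """
    if n_types < 2:
        raise ValueError("need at least 2 cell types")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    if n_genes < 5 * n_types:
        raise ValueError(f"need n_genes >= 5*n_types ({5 * n_types}), got {n_genes}")
    rng = np.random.default_rng(seed)
    block = n_genes // n_types
    step = max(1, int(round(block * (1.0 - overlap))))
    genes = [f"G{i:05d}" for i in range(n_genes)]
    types = [f"CT{i + 1:02d}" for i in range(n_types)]
    base = base_level * rng.lognormal(mean=0.0, sigma=0.3, size=(n_genes, n_types))
    amp = marker_fold * rng.lognormal(mean=0.0, sigma=0.25, size=n_genes)
    B = pd.DataFrame(base, index=genes, columns=types)
    markers: dict[str, list[str]] = {}
    for t in range(n_types):
        start = t * step
        rows = np.arange(start, min(start + block, n_genes))
        B.iloc[rows, t] = base_level * amp[rows] * rng.lognormal(0.0, 0.1, size=rows.size)
        markers[types[t]] = [genes[i] for i in rows]
    B.attrs["markers"] = markers
    return B


def make_mixtures(
    B: pd.DataFrame,
    n_samples: int,
    dirichlet_alpha=1.0,
    noise_sd: float = 0.0,
    scale: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Bulk mixtures m_s = B·f_s with multiplicative lognormal noise.

    Fractions are drawn per sample from Dirichlet(``dirichlet_alpha``);
    ``noise_sd`` is the sigma of the lognormal noise factor applied per gene
    (0 = noiseless).  Returns the genes × samples matrix and the ground truth.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n_types = B.shape[1]
    alpha = np.full(n_types, float(dirichlet_alpha)) if np.isscalar(dirichlet_alpha) \
        else np.asarray(dirichlet_alpha, dtype=float)
    F = rng.dirichlet(alpha, size=n_samples)  # samples × types
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    M = B.to_numpy() @ F.T * scale
    if noise_sd > 0:
        M = M * rng.lognormal(mean=0.0, sigma=noise_sd, size=M.shape)
    mix = pd.DataFrame(M, index=B.index, columns=samples)
    truth = GroundTruth(
        seed=seed,
        fractions=pd.DataFrame(F, index=samples, columns=B.columns),
        noise={"noise_sd": noise_sd, "dirichlet_alpha": float(np.mean(alpha)), "scale": scale},
    )
    return mix, truth


def make_flow(truth: GroundTruth, cv: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Pseudo-flow panel: 100·fraction with multiplicative Gaussian noise.

    ``cv`` is the coefficient of variation of the measurement; values are
    clipped into [0, 100] as percentages of the parent population.
    """
    if truth.fractions is None:
        raise ValueError("ground truth carries no fractions")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    pct = 100.0 * truth.fractions.to_numpy()
    if cv > 0:
        pct = pct * (1.0 + rng.normal(0.0, cv, size=pct.shape))
    pct = np.clip(pct, 0.0, 100.0)
    return pd.DataFrame(pct, index=truth.fractions.index, columns=truth.fractions.columns)


def identity_mapping(cell_types) -> pd.DataFrame:
    """Trivial mapping pairing each cell type's score with its own flow column."""
    return pd.DataFrame({"signature_id": list(cell_types), "flow_phenotype": list(cell_types)})


def make_cohort(
    n_per_arm=DEFAULT_ARM_SIZES,
    effects: dict[str, tuple[str, float]] | None = None,
    age_range: tuple[float, float] = (25.0, 55.0),
    gender_balance: float = 0.886,
    seed: int = 0,
    n_signatures: int = 40,
    noise_sd: float = 1.0,
    baseline_mean: float = 10.0,
    age_effects: dict[str, float] | None = None,
    gender_effects: dict[str, float] | None = None,
    age_shift_by_arm: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Three-arm cohort table with injected treatment effects.

    ``effects`` maps signature name → (contrast, delta): samples in the
    contrast's treated arm(s) have ``delta`` (in units of ``noise_sd``) added
    to that signature.  ``age_effects`` / ``gender_effects`` add linear age
    slopes and female-vs-male shifts; ``age_shift_by_arm`` biases arm mean
    ages to construct confounded designs on purpose.  ``gender_balance`` is
    the female fraction.  Defaults mirror the trial subset the pipeline
    targets: arm sizes (57, 62, 70) and a female-dominated cohort.
    """
    if np.isscalar(n_per_arm):
        if n_per_arm < 10:
            raise ValueError("need n_per_arm >= 10")
        n_per_arm = (int(n_per_arm),) * 3
    if len(n_per_arm) != 3 or min(n_per_arm) < 10:
        raise ValueError("n_per_arm must be one int or three ints, each >= 10")
    effects = dict(effects or {})
    rng = np.random.default_rng(seed)
    arms = ["placebo"] * n_per_arm[0] + ["low_dose"] * n_per_arm[1] + ["high_dose"] * n_per_arm[2]
    n = len(arms)
    samples = [f"P{i + 1:04d}" for i in range(n)]
    sigs = [f"sig{i + 1:02d}" for i in range(n_signatures)]
    unknown = [s for s in effects if s not in sigs]
    if unknown:
        raise ValueError(f"effects reference unknown signatures: {unknown}")

    age = rng.uniform(*age_range, size=n)
    if age_shift_by_arm:
        age = age + np.array([age_shift_by_arm.get(a, 0.0) for a in arms])
    gender = np.where(rng.uniform(size=n) < gender_balance, "F", "M")

    cohort = pd.DataFrame({"arm": arms, "age": age, "gender": gender}, index=samples)
    cohort.index.name = "sample_id"
    baseline = rng.normal(baseline_mean, 1.0, size=n_signatures)
    for j, sig in enumerate(sigs):
        score = baseline[j] + rng.normal(0.0, noise_sd, size=n)
        if sig in effects:
            contrast, delta = effects[sig]
            treated = np.isin(arms, _TREATED_ARMS[contrast])
            score = score + treated * delta * noise_sd
        if age_effects and sig in age_effects:
            score = score + age_effects[sig] * (age - np.mean(age))
        if gender_effects and sig in gender_effects:
            score = score + gender_effects[sig] * (gender == "F")
        cohort[sig] = score

    truth = GroundTruth(seed=seed, effects=effects,
                        noise={"noise_sd": noise_sd, "gender_balance": gender_balance})
    return cohort, truth


def write_preset(preset: str, outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a ready-to-run input bundle plus ground-truth JSON.

    ``validation``: signature matrix, 50 noisy mixtures, matched pseudo-flow
    panel and identity mapping — everything needed for a deconvolve→validate
    run.  ``cohort``: a three-arm cohort table with five injected effects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if preset == "validation":
        B = make_signature_matrix(150, 5, overlap=0.1, seed=seed)
        mix, truth = make_mixtures(B, 50, noise_sd=0.05, seed=seed + 1)
        flow = make_flow(truth, cv=0.05, seed=seed + 2)
        mapping = identity_mapping(B.columns)
        paths["signature"] = outdir / "signature.tsv"
        io.write_expression(B, paths["signature"], {"role": "signature_matrix", "seed": seed})
        paths["mixture"] = outdir / "mixture.tsv"
        io.write_expression(mix, paths["mixture"], {"role": "mixture", "seed": seed + 1})
        paths["flow"] = outdir / "flow.csv"
        io.write_flow(flow, paths["flow"], {"role": "pseudo_flow", "seed": seed + 2})
        paths["mapping"] = outdir / "mapping.tsv"
        mapping.to_csv(paths["mapping"], sep="\t", index=False)
        paths["truth"] = outdir / "truth.json"
        truth.to_json(paths["truth"])
    elif preset == "cohort":
        effects = {f"sig{i:02d}": ("combined_vs_placebo", 1.0) for i in (3, 9, 17, 25, 33)}
        cohort, truth = make_cohort(effects=effects, seed=seed)
        paths["cohort"] = outdir / "cohort.csv"
        cohort.to_csv(paths["cohort"])
        paths["truth"] = outdir / "truth.json"
        truth.to_json(paths["truth"])
    else:
        raise ValueError(f"unknown preset {preset!r}; expected 'validation' or 'cohort'")
    return paths
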