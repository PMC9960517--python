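"""Synthetic cohort simulation with known causal architecture.

The generator emulates the kind of multi-cohort array data the downstream
pipeline consumes: a quantitative phenotype driven by a configurable number
of causal SNPs at a configurable heritability, covariates (sex, age and two
binary disease statuses), optional discrete population structure
(Balding-Nichols allele-frequency divergence), first-order LD between
adjacent variants, and random missing calls. A companion
:func:`perturb_for_merge` produces a second-cohort "view" of the same data
with strand flips, allele switches, panel-unique and unresolvable variants,
together with a manifest that lets tests verify harmonization exactly.

Model
-----
Per variant j an ancestral allele frequency ``p_j ~ U(maf_range)`` is drawn.
With ``n_pops > 1`` each population k receives
``p_jk ~ Beta(p_j (1-F)/F, (1-p_j)(1-F)/F)`` (Balding-Nichols, F = fst).
Haplotypes are drawn by thresholding a stationary AR(1) Gaussian process
(lag-1 correlation ``ld_rho``, reset at chromosome boundaries), so adjacent
variants are correlated and clumping/regression-imputation have signal to
work with. Causal effects are N(0, h2/n_causal) on the standardized-genotype
scale, then de-standardized; the Gaussian noise variance is solved from the
realized genetic and covariate variances so that the genetic fraction of
total phenotypic variance targets ``heritability``.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from ._rng import substream
from .genio import MISSING, GenotypeDataset

__all__ = [
    "CohortSpec",
    "TruthRecord",
    "simulate_cohort",
    "perturb_for_merge",
    "bmi",
    "bmi_class",
    "COMPLEMENT",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: allele pairs used by the simulator; palindromic (A/T, C/G) pairs are
#: excluded so that strand flips are always resolvable in synthetic data.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

#: default covariate effect sizes, phenotype units per covariate unit
DEFAULT_COVARIATE_EFFECTS: Mapping[str, float] = {
    "sex": 0.5,
    "age": 0.02,
    "status1": 0.4,
    "status2": 0.3,
}


@dataclasses.dataclass
class CohortSpec:
    """Parameters of one simulated cohort."""

    n_samples: int
    n_snps: int
    n_causal: int = 0
    heritability: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    n_pops: int = 1
    fst: float = 0.0
    ld_rho: float = 0.3
    n_chroms: int = 10
    bp_spacing: int = 3_000
    covariate_effects: Mapping[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_snps", "n_causal", "n_pops", "n_chroms", "bp_spacing"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)):
                raise ValueError(f"{name} must be an integer count, got {v!r}")
        if self.n_samples < 1 or self.n_snps < 1:
            raise ValueError("n_samples and n_snps must be positive")
        if self.n_causal < 0 or self.n_causal > self.n_snps:
            raise ValueError(f"n_causal must be in [0, n_snps], got {self.n_causal}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie inside (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError(f"heritability must be in [0, 1], got {self.heritability}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if not -0.99 <= self.ld_rho <= 0.99:
            raise ValueError(f"ld_rho must be in [-0.99, 0.99], got {self.ld_rho}")
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")


@dataclasses.dataclass
class TruthRecord:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    causal_variant_ids: list[str]
    true_betas: np.ndarray
    heritability: float
    covariate_effects: Mapping[str, float]
    population_labels: np.ndarray

    def genetic_values(self, dataset: GenotypeDataset) -> np.ndarray:
        """True per-sample genetic score (missing dosages counted as 0)."""
        idx = dataset.variants.set_index("id").index.get_indexer(self.causal_variant_ids)
        if (idx < 0).any():
            raise ValueError("causal variant missing from dataset")
        d = dataset.dosages[:, idx].astype(float)
        d[d == MISSING] = 0.0
        return d @ np.asarray(self.true_betas, float)


def _ar1_latents(rng: np.random.Generator, n_draws: int, m: int, rho: float) -> np.ndarray:
    """Stationary AR(1) N(0,1) latent field, shape (n_draws, m)."""
    eps = rng.standard_normal((n_draws, m))
    if abs(rho) < 1e-12 or m == 1:
        return eps
    x = eps * np.sqrt(1.0 - rho**2)
    x[:, 0] = eps[:, 0]
    # y[j] = rho * y[j-1] + x[j]
    return signal.lfilter([1.0], [1.0, -rho], x, axis=1)


def simulate_cohort(spec: CohortSpec) -> tuple[GenotypeDataset, TruthRecord]:
    """Draw one cohort and its ground truth from ``spec``."""
    spec.validate()
    n, m = spec.n_samples, spec.n_snps
    rng_g = substream(spec.seed, "genotypes")
    rng_e = substream(spec.seed, "effects")
    rng_n = substream(spec.seed, "noise")
    rng_m = substream(spec.seed, "missingness")
    rng_c = substream(spec.seed, "covariates")

    # variant map: n_chroms equal blocks, evenly spaced positions
    n_chroms = min(spec.n_chroms, m)
    chrom_of = np.minimum(np.arange(m) * n_chroms // m, n_chroms - 1)
    pos = np.empty(m, dtype=np.int64)
    for c in range(n_chroms):
        block = np.flatnonzero(chrom_of == c)
        pos[block] = (np.arange(block.size) + 1) * spec.bp_spacing
    pair_idx = rng_g.integers(0, len(_ALLELE_PAIRS), size=m)
    variants = pd.DataFrame(
        {
            "id": [f"snp{j:06d}" for j in range(m)],
            "chrom": [str(c + 1) for c in chrom_of],
            "pos": pos,
            "allele1": [_ALLELE_PAIRS[k][0] for k in pair_idx],
            "allele2": [_ALLELE_PAIRS[k][1] for k in pair_idx],
        }
    )

    # allele frequencies: ancestral, then per-population Balding-Nichols
    lo, hi = spec.maf_range
    p_anc = rng_g.uniform(lo, hi, size=m)
    pops = rng_g.integers(0, spec.n_pops, size=n)
    if spec.n_pops > 1 and spec.fst > 0:
        F = spec.fst
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        p_pop = np.clip(rng_g.beta(a[None, :], b[None, :], size=(spec.n_pops, m)), 1e-4, 1 - 1e-4)
    else:
        p_pop = np.tile(p_anc, (spec.n_pops, 1))

    # two haplotypes per sample via AR(1) Gaussian copula, reset per chromosome
    thresh = stats.norm.ppf(p_pop)  # (n_pops, m)
    dosages = np.zeros((n, m), dtype=np.int8)
    for _hap in range(2):
        z = np.empty((n, m))
        for c in range(n_chroms):
            block = np.flatnonzero(chrom_of == c)
            z[:, block] = _ar1_latents(rng_g, n, block.size, spec.ld_rho)
        dosages += (z < thresh[pops, :]).astype(np.int8)

    # causal architecture
    causal_idx = np.sort(rng_e.choice(m, size=spec.n_causal, replace=False))
    betas_std = rng_e.normal(
        0.0,
        np.sqrt(spec.heritability / spec.n_causal) if spec.n_causal else 0.0,
        size=spec.n_causal,
    )
    sd_geno = np.sqrt(2.0 * p_anc[causal_idx] * (1.0 - p_anc[causal_idx]))
    true_betas = betas_std / sd_geno
    g = dosages[:, causal_idx].astype(float) @ true_betas if spec.n_causal else np.zeros(n)

    # covariates
    effects = dict(spec.covariate_effects) if spec.covariate_effects is not None else dict(DEFAULT_COVARIATE_EFFECTS)
    cov = pd.DataFrame(
        {
            "sex": rng_c.integers(0, 2, size=n).astype(float),
            "age": rng_c.normal(53.0, 10.0, size=n),
            "status1": (rng_c.random(n) < 0.3).astype(float),
            "status2": (rng_c.random(n) < 0.2).astype(float),
        },
        index=[f"S{i:05d}" for i in range(n)],
    )
    cov_term = sum(effects.get(c, 0.0) * cov[c].to_numpy() for c in cov.columns)
    cov_term = np.asarray(cov_term, float)

    # noise scaled so realized var(g) / var(phenotype) targets heritability
    var_g = float(np.var(g))
    var_c = float(np.var(cov_term))
    h2 = spec.heritability
    if h2 > 0 and var_g > 0:
        var_noise = var_g * (1.0 - h2) / h2 - var_c
        if var_noise < 0:
            warnings.warn(
                "covariate variance exceeds the non-genetic budget at this heritability; "
                "realized heritability will fall below target"
            )
            var_noise = 0.05 * var_g
    else:
        var_noise = max(1.0 - var_c, 0.1)
    noise = rng_n.normal(0.0, np.sqrt(var_noise), size=n)
    phenotype = g + cov_term + noise

    pheno = cov.copy()
    pheno.insert(0, "phenotype", phenotype)

    # missing calls
    if spec.missing_rate > 0:
        mask = rng_m.random((n, m)) < spec.missing_rate
        dosages[mask] = MISSING

    dataset = GenotypeDataset(list(cov.index), variants, dosages, phenotable=pheno)
    truth = TruthRecord(
        causal_variant_ids=[variants["id"].iloc[j] for j in causal_idx],
        true_betas=true_betas,
        heritability=h2,
        covariate_effects=effects,
        population_labels=pops,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Harmonization-defect perturbation
# ---------------------------------------------------------------------------

def perturb_for_merge(
    dataset: GenotypeDataset,
    frac_flip: float = 0.0,
    frac_switch: float = 0.0,
    frac_unique: float = 0.0,
    frac_unresolvable: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Produce a second-cohort view of ``dataset`` with harmonization defects.

    Disjoint random subsets of variants are strand-flipped (alleles
    complemented, dosages unchanged), allele-switched (allele order and
    dosage coding reversed), dropped (panel-unique to the input cohort) or
    rewritten to an unresolvable allele pair. Returns the perturbed dataset
    and a manifest DataFrame (variant_id, action, old/new alleles) that lets
    a test apply the inverse of each perturbation and recover the original.
    """
    fracs = (frac_flip, frac_switch, frac_unique, frac_unresolvable)
    if any(f < 0 or f > 1 for f in fracs):
        raise ValueError("perturbation fractions must be in [0, 1]")
    if sum(fracs) > 1.0 + 1e-12:
        raise ValueError(f"perturbation fractions must sum to <= 1, got {sum(fracs)}")

    m = dataset.n_variants
    rng = substream(seed, "perturb")
    order = rng.permutation(m)
    k_flip, k_switch, k_unique, k_unres = (int(round(f * m)) for f in fracs)
    flip_idx = order[:k_flip]
    switch_idx = order[k_flip : k_flip + k_switch]
    unique_idx = order[k_flip + k_switch : k_flip + k_switch + k_unique]
    unres_idx = order[k_flip + k_switch + k_unique : k_flip + k_switch + k_unique + k_unres]

    variants = dataset.variants.copy()
    dosages = dataset.dosages.copy()
    rows = []

    for j in flip_idx:
        a1, a2 = variants.loc[j, ["allele1", "allele2"]]
        na1, na2 = COMPLEMENT[a1], COMPLEMENT[a2]
        variants.loc[j, ["allele1", "allele2"]] = [na1, na2]
        rows.append((variants.loc[j, "id"], "flip", a1, a2, na1, na2))
    for j in switch_idx:
        a1, a2 = variants.loc[j, ["allele1", "allele2"]]
        variants.loc[j, ["allele1", "allele2"]] = [a2, a1]
        col = dosages[:, j]
        obs = col != MISSING
        col[obs] = 2 - col[obs]
        rows.append((variants.loc[j, "id"], "switch", a1, a2, a2, a1))
    for j in unres_idx:
        a1, a2 = variants.loc[j, ["allele1", "allele2"]]
        # pick a pair that is neither identical, swapped, nor a strand image
        forbidden = {(a1, a2), (a2, a1), (COMPLEMENT[a1], COMPLEMENT[a2]), (COMPLEMENT[a2], COMPLEMENT[a1])}
        candidates = [p for p in _ALLELE_PAIRS if p not in forbidden]
        na1, na2 = candidates[rng.integers(0, len(candidates))]
        variants.loc[j, ["allele1", "allele2"]] = [na1, na2]
        rows.append((variants.loc[j, "id"], "unresolvable", a1, a2, na1, na2))
    for j in unique_idx:
        a1, a2 = variants.loc[j, ["allele1", "allele2"]]
        rows.append((variants.loc[j, "id"], "unique_a", a1, a2, "", ""))

    keep = np.setdiff1d(np.arange(m), unique_idx)
    manifest = pd.DataFrame(
        rows, columns=["variant_id", "action", "old_allele1", "old_allele2", "new_allele1", "new_allele2"]
    )
    out = GenotypeDataset(
        dataset.sample_ids,
        variants.iloc[keep],
        dosages[:, keep],
        dataset.phenotable,
        None if dataset.info_scores is None else dataset.info_scores[keep],
    )
    return out, manifest


# ---------------------------------------------------------------------------
# BMI helpers
# ---------------------------------------------------------------------------

def bmi(weight_kg: float, height_m: float) -> float:
    """Body-mass index, kg/m^2."""
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    return weight_kg / height_m**2


def bmi_class(value: float) -> str:
    """WHO category at the 18.5 / 25 / 30 kg/m^2 cut-points."""
    if value < 18.5:
        return "underweight"
    if value < 25.0:
        return "normal"
    if value < 30.0:
        return "overweight"
    return "obese"
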