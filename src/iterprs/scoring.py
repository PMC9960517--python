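"""PRS computation, clumping + p-value thresholding, and the PRS R^2 metric.

The score for sample s is ``sum_i w_i G_si / D`` where G counts copies of
the model's effect allele and the denominator D depends on the
normalization mode: the literal sample count, twice the per-sample count of
non-missing model variants (the per-allele average convention of common PRS
tooling), or 1. All three are positive affine transforms of each other on
complete data, so the incremental-R^2 metric and min-max-normalized scores
are identical across modes.

PRS R^2 is the increment in the coefficient of determination when the score
is added to a covariate-only regression: R^2(full) - R^2(reduced).

Model search is clumping + thresholding (C+T): greedily prune variants in
LD (r^2 > r2_max within window_kb) keeping the smallest-p representative,
then scan a p-value threshold grid and keep the threshold maximizing the
PRS R^2 on the target samples; ties resolve toward the stricter threshold
(fewer SNPs).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import SummaryStats
from .genio import MISSING, GenotypeDataset
from .simcohort import COMPLEMENT

__all__ = [
    "PRSModel",
    "PRSFit",
    "compute_prs",
    "minmax_normalize",
    "clump",
    "prs_r2",
    "ct_search",
    "DEFAULT_THRESHOLDS",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)

DENOMINATOR_MODES = ("allele_count", "n_samples_literal", "none")


@dataclasses.dataclass
class PRSModel:
    """Ordered (variant id, effect allele, weight) triples plus scoring mode."""

    entries: pd.DataFrame  # columns: id, effect_allele, weight
    denominator_mode: str = "allele_count"
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        needed = {"id", "effect_allele", "weight"}
        if not needed <= set(self.entries.columns):
            raise ValueError(f"model entries need columns {sorted(needed)}")
        if self.entries["id"].duplicated().any():
            raise ValueError("duplicate variant ids in PRS model")
        if not np.isfinite(self.entries["weight"].to_numpy(float)).all():
            raise ValueError("model weights must be finite")
        if self.denominator_mode not in DENOMINATOR_MODES:
            raise ValueError(f"denominator_mode must be one of {DENOMINATOR_MODES}")

    @property
    def n_snps(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return self.entries[["id", "effect_allele", "weight"]].copy()


@dataclasses.dataclass
class PRSFit:
    """Fit of one PRS on one evaluation set."""

    prs_r2: float
    p_value: float
    beta_prs: float
    n_snps: int
    threshold: float | None = None

    def validate(self) -> None:
        if self.prs_r2 < 0:
            raise ValueError("prs_r2 must be non-negative")
        if self.n_snps < 1:
            raise ValueError("a fitted PRS must contain at least one SNP")


def _orient_weights(dataset: GenotypeDataset, model: PRSModel) -> tuple[np.ndarray, np.ndarray]:
    """Match model entries to dataset columns, reconciling effect alleles.

    Returns (column indices, signed orientation) where orientation +1 means
    the dataset's allele1 is the model's effect allele (count dosage as-is)
    and -1 means it is the other allele (count 2 - dosage). Strand images
    (complemented alleles) are accepted for non-palindromic variants.
    """
    vidx = {vid: j for j, vid in enumerate(dataset.variants["id"])}
    a1 = dataset.variants["allele1"].to_numpy(str)
    a2 = dataset.variants["allele2"].to_numpy(str)
    cols, orient = [], []
    skipped = 0
    for row in model.entries.itertuples(index=False):
        j = vidx.get(row.id)
        if j is None:
            skipped += 1
            continue
        ea = str(row.effect_allele)
        if ea == a1[j] or (COMPLEMENT.get(ea) == a1[j] and COMPLEMENT.get(a1[j]) != a2[j]):
            cols.append(j)
            orient.append(1)
        elif ea == a2[j] or (COMPLEMENT.get(ea) == a2[j] and COMPLEMENT.get(a1[j]) != a2[j]):
            cols.append(j)
            orient.append(-1)
        else:
            skipped += 1
    if skipped:
        warnings.warn(f"{skipped} model variants absent or allele-irreconcilable; skipped")
    if not cols:
        raise ValueError("no model variant could be matched to the dataset")
    return np.asarray(cols), np.asarray(orient)


def compute_prs(dataset: GenotypeDataset, model: PRSModel) -> np.ndarray:
    """Per-sample raw polygenic score under the model's denominator mode."""
    cols, orient = _orient_weights(dataset, model)
    matched_ids = dataset.variants["id"].iloc[cols]
    w = model.entries.set_index("id").loc[matched_ids, "weight"].to_numpy(float)
    d = dataset.dosages[:, cols].astype(np.float64)
    obs = d != MISSING
    g = np.where(obs, d, 0.0)
    g = np.where(orient > 0, g, np.where(obs, 2.0 - g, 0.0))
    raw = g @ w
    if model.denominator_mode == "n_samples_literal":
        return raw / dataset.n_samples
    if model.denominator_mode == "allele_count":
        denom = 2.0 * obs.sum(axis=1)
        if (denom == 0).any():
            warnings.warn("samples with zero non-missing model variants score 0")
        return np.where(denom > 0, raw / np.where(denom > 0, denom, 1.0), 0.0)
    return raw


def minmax_normalize(scores: np.ndarray) -> np.ndarray:
    """Scale scores to [0, 1]; a constant vector maps to all 0.5."""
    s = np.asarray(scores, float)
    lo, hi = float(np.min(s)), float(np.max(s))
    if hi == lo:
        warnings.warn("constant score vector; min-max normalization returns 0.5")
        return np.full_like(s, 0.5)
    return (s - lo) / (hi - lo)


def clump(
    sumstats: SummaryStats | pd.DataFrame,
    dataset: GenotypeDataset,
    r2_max: float = 0.1,
    window_kb: float = 250.0,
) -> list[str]:
    """Greedy LD clumping: keep the smallest-p variant of each LD cluster.

    Variants are visited in ascending p; a variant is accepted unless its
    dosage r^2 with an already-accepted variant within ``window_kb`` on the
    same chromosome exceeds ``r2_max``. LD is computed from the dataset's
    dosages (missing calls mean-imputed for the correlation).
    """
    import bisect

    table = sumstats.table if isinstance(sumstats, SummaryStats) else sumstats
    vidx = {vid: j for j, vid in enumerate(dataset.variants["id"])}
    unknown = [v for v in table["id"] if v not in vidx]
    if unknown:
        raise ValueError(f"{len(unknown)} summary-stat variants absent from dataset (e.g. {unknown[:3]})")

    # unit-normalized centered dosage columns: r = plain dot product
    d = dataset.dosages.astype(np.float64)
    d[d == MISSING] = np.nan
    col_mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_mean, d)
    d -= d.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", d, d))
    norms[norms == 0] = np.inf  # monomorphic: correlates with nothing
    d /= norms

    order = table.sort_values(["p", "id"], kind="stable")
    window = window_kb * 1000.0
    # per chrom: accepted positions kept sorted, with parallel column list
    acc_pos: dict[str, list[int]] = {}
    acc_col: dict[str, list[int]] = {}
    kept: list[str] = []
    chroms = dataset.variants["chrom"].to_numpy(str)
    poss = dataset.variants["pos"].to_numpy()
    for row in order.itertuples(index=False):
        j = vidx[row.id]
        c, p_j = chroms[j], int(poss[j])
        pos_list = acc_pos.setdefault(c, [])
        col_list = acc_col.setdefault(c, [])
        lo = bisect.bisect_left(pos_list, p_j - window)
        hi = bisect.bisect_right(pos_list, p_j + window)
        ok = True
        if hi > lo:
            r = d[:, col_list[lo:hi]].T @ d[:, j]
            ok = not bool((r * r > r2_max).any())
        if ok:
            kept.append(row.id)
            at = bisect.bisect_left(pos_list, p_j)
            pos_list.insert(at, p_j)
            col_list.insert(at, j)
    return kept


def prs_r2(
    scores: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    n_snps: int = 1,
    threshold: float | None = None,
) -> PRSFit:
    """Incremental R^2 of the PRS over the covariate-only model.

    Fits phenotype ~ covariates + PRS (full) and phenotype ~ covariates
    (reduced); returns R^2(full) - R^2(reduced) with the PRS coefficient's
    estimate and t-test p-value from the full model.
    """
    y = np.asarray(phenotype, float)
    s = np.asarray(scores, float)
    n = y.size
    if covariates is None or np.size(covariates) == 0:
        C = np.ones((n, 1))
    else:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n:
            C = C.T
        C = np.column_stack([np.ones(n), C])
    if n <= C.shape[1] + 1:
        raise ValueError("fewer samples than regression parameters")

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("constant phenotype")

    Q, _ = np.linalg.qr(C)
    ry = y - Q @ (Q.T @ y)
    rs = s - Q @ (Q.T @ s)
    rss_red = float(ry @ ry)
    gg = float(rs @ rs)
    if gg <= 1e-12 * n:
        # score collinear with covariates: adds nothing
        return PRSFit(prs_r2=0.0, p_value=1.0, beta_prs=0.0, n_snps=n_snps, threshold=threshold)
    beta = float(rs @ ry) / gg
    rss_full = rss_red - beta**2 * gg
    r2_inc = (rss_red - rss_full) / ss_tot
    df = n - C.shape[1] - 1
    sigma2 = max(rss_full, 0.0) / df
    se = np.sqrt(sigma2 / gg)
    if se > 0:
        p = float(2.0 * stats.t.sf(abs(beta / se), df))
    else:
        p = np.nextafter(0, 1)
    fit = PRSFit(prs_r2=max(float(r2_inc), 0.0), p_value=max(p, np.nextafter(0, 1)),
                 beta_prs=beta, n_snps=n_snps, threshold=threshold)
    fit.validate()
    return fit


def ct_search(
    sumstats: SummaryStats,
    target: GenotypeDataset,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    phenotype_name: str = "phenotype",
    covariates: Sequence[str] = ("sex", "age", "status1", "status2"),
    pcs: np.ndarray | None = None,
    r2_max: float = 0.1,
    window_kb: float = 250.0,
    denominator_mode: str = "allele_count",
) -> tuple[PRSModel, PRSFit]:
    """Clumping + thresholding model search on the target samples.

    Clump once, then for each p-value threshold build the model from the
    clumped variants with p <= threshold (weights = betas), score the
    target, and keep the threshold maximizing the incremental R^2. Ties
    break toward the stricter threshold, i.e. fewer SNPs.
    """
    table = sumstats.table
    kept = clump(sumstats, target, r2_max=r2_max, window_kb=window_kb)
    clumped = table[table["id"].isin(set(kept))]

    if target.phenotable is None:
        raise ValueError("target dataset has no phenotype table")
    tab = target.phenotable.loc[target.sample_ids]
    y = tab[phenotype_name].to_numpy(float)
    C = np.column_stack([tab[c].to_numpy(float) for c in covariates]) if covariates else None
    if pcs is not None and np.size(pcs):
        P = np.atleast_2d(np.asarray(pcs, float))
        C = P if C is None else np.hstack([C, P])

    best: tuple[PRSModel, PRSFit] | None = None
    for thr in sorted(thresholds):
        sel = clumped[clumped["p"] <= thr]
        if sel.empty:
            continue
        entries = pd.DataFrame(
            {"id": sel["id"].to_numpy(), "effect_allele": sel["effect_allele"].to_numpy(),
             "weight": sel["beta"].to_numpy(float)}
        )
        model = PRSModel(entries, denominator_mode=denominator_mode,
                         provenance={"engine": sumstats.engine, "threshold": thr})
        scores = compute_prs(target, model)
        fit = prs_r2(scores, y, C, n_snps=model.n_snps, threshold=thr)
        if best is None or fit.prs_r2 > best[1].prs_r2:
            best = (model, fit)
    if best is None:
        raise ValueError("no variant passes even the loosest threshold")
    return best
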