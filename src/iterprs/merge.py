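"""Harmonization and merging of two genotype datasets, plus missingness fill.

Two array cohorts rarely share a panel representation: the same variant may
be reported on opposite strands (alleles complemented) or with the counted
allele reversed (dosage d -> 2-d). :func:`classify_variants` sorts the union
of variants into identical / flip / switch / drop / cohort-unique classes,
:func:`merge_datasets` applies the plan, and the two imputation passes
(:func:`impute_regression` over LD neighbors, then :func:`impute_knn`) fill
the missingness the union creates.

Palindromic (A/T, C/G) variants are ambiguous under strand flipping and are
always dropped. An optional offline allele-authority map (variant id ->
risk allele) can rescue otherwise unresolvable variants, standing in for
online annotation lookups.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeDataset
from .simcohort import COMPLEMENT

__all__ = [
    "MergePlan",
    "classify_variants",
    "merge_datasets",
    "impute_regression",
    "impute_knn",
    "is_palindromic",
]

log = logging.getLogger(__name__)


def is_palindromic(a1: str, a2: str) -> bool:
    """True for strand-ambiguous allele pairs (A/T and C/G)."""
    return COMPLEMENT.get(a1) == a2


@dataclasses.dataclass
class MergePlan:
    """Partition of the variant-id union of two datasets.

    ``flip_also_switch`` is an auxiliary subset of ``flip``: variants whose
    alleles match only after complementing *and* swapping cohort B's pair,
    so B's dosages additionally need the 2-d recode.
    """

    identical: list[str]
    flip: list[str]
    switch: list[str]
    drop: list[str]
    unique_a: list[str]
    unique_b: list[str]
    flip_also_switch: set[str] = dataclasses.field(default_factory=set)

    def all_ids(self) -> list[str]:
        return self.identical + self.flip + self.switch + self.drop + self.unique_a + self.unique_b

    def validate(self) -> None:
        ids = self.all_ids()
        if len(ids) != len(set(ids)):
            raise ValueError("merge plan classes overlap")
        if not self.flip_also_switch <= set(self.flip):
            raise ValueError("flip_also_switch must be a subset of flip")


def classify_variants(a: GenotypeDataset, b: GenotypeDataset) -> MergePlan:
    """Classify each variant in the union of ``a`` and ``b`` panels.

    Shared variants (same id) must agree on position; their allele pairs are
    compared in four orientations: identical, strand-flipped, switched
    (order reversed), or flipped+switched. Anything else, and any
    palindromic pair, is dropped.
    """
    va = a.variants.set_index("id")
    vb = b.variants.set_index("id")
    shared = [i for i in va.index if i in vb.index]
    shared_set = set(shared)

    plan = MergePlan([], [], [], [], [], [])
    for vid in shared:
        ra, rb = va.loc[vid], vb.loc[vid]
        if (str(ra["chrom"]), int(ra["pos"])) != (str(rb["chrom"]), int(rb["pos"])):
            raise ValueError(
                f"variant {vid}: conflicting coordinates "
                f"({ra['chrom']}:{ra['pos']} vs {rb['chrom']}:{rb['pos']})"
            )
        a1, a2 = str(ra["allele1"]), str(ra["allele2"])
        b1, b2 = str(rb["allele1"]), str(rb["allele2"])
        if is_palindromic(a1, a2) or is_palindromic(b1, b2):
            plan.drop.append(vid)
            continue
        f1, f2 = COMPLEMENT.get(b1), COMPLEMENT.get(b2)
        if (b1, b2) == (a1, a2):
            plan.identical.append(vid)
        elif (f1, f2) == (a1, a2):
            plan.flip.append(vid)
        elif (b2, b1) == (a1, a2):
            plan.switch.append(vid)
        elif (f2, f1) == (a1, a2):
            plan.flip.append(vid)
            plan.flip_also_switch.add(vid)
        else:
            plan.drop.append(vid)
    plan.unique_a = [i for i in va.index if i not in shared_set]
    plan.unique_b = [i for i in vb.index if i not in shared_set]
    plan.validate()
    return plan


def _chrom_sort_key(chrom: pd.Series | np.ndarray) -> np.ndarray:
    """Integer ranks implementing numeric-aware chromosome ordering
    (1..22 before X, Y, ...)."""
    def key(c: str) -> tuple[int, str]:
        try:
            return (int(c), "")
        except ValueError:
            return (10_000, c)

    values = [str(c) for c in chrom]
    ranks = {c: i for i, c in enumerate(sorted(set(values), key=key))}
    return np.array([ranks[c] for c in values])


def merge_datasets(
    a: GenotypeDataset,
    b: GenotypeDataset,
    plan: MergePlan | None = None,
    cohort_names: tuple[str, str] = ("A", "B"),
    on_duplicate_samples: str = "error",
) -> GenotypeDataset:
    """Merge two cohorts per a :class:`MergePlan`.

    Cohort A's variant records are canonical for shared variants; cohort B
    dosages at switch-class variants (and flip-also-switch) are recoded
    d -> 2-d. The output holds the union of samples and of retained
    variants, sorted by (chrom, pos); genotypes absent in a source cohort
    are missing. A ``cohort`` provenance column is added to the phenotable.
    """
    if plan is None:
        plan = classify_variants(a, b)
    plan.validate()

    dup = set(a.sample_ids) & set(b.sample_ids)
    if dup:
        if on_duplicate_samples == "error":
            raise ValueError(
                f"{len(dup)} duplicate sample ids across cohorts (e.g. {sorted(dup)[:3]}); "
                "pass on_duplicate_samples='suffix' to rename"
            )
        if on_duplicate_samples != "suffix":
            raise ValueError("on_duplicate_samples must be 'error' or 'suffix'")

    shared_ids = plan.identical + plan.flip + plan.switch
    keep_a = shared_ids + plan.unique_a
    keep_b_only = plan.unique_b

    va = a.variants.set_index("id")
    vb = b.variants.set_index("id")
    variants = pd.concat([va.loc[keep_a], vb.loc[keep_b_only]]).reset_index()

    # recode cohort B dosages that need the allele switch
    recode = set(plan.switch) | plan.flip_also_switch
    b_dos = b.dosages.copy()
    b_col = {vid: j for j, vid in enumerate(b.variants["id"])}
    for vid in recode:
        col = b_dos[:, b_col[vid]]
        obs = col != MISSING
        col[obs] = 2 - col[obs]

    n_a, n_b = a.n_samples, b.n_samples
    m = len(variants)
    out = np.full((n_a + n_b, m), MISSING, dtype=np.int8)
    a_col = {vid: j for j, vid in enumerate(a.variants["id"])}
    for jo, vid in enumerate(variants["id"]):
        if vid in a_col:
            out[:n_a, jo] = a.dosages[:, a_col[vid]]
        if vid in b_col:
            out[n_a:, jo] = b_dos[:, b_col[vid]]

    # info scores: prefer cohort A's where both report one
    info = None
    if a.info_scores is not None or b.info_scores is not None:
        info = np.full(m, np.nan)
        for jo, vid in enumerate(variants["id"]):
            if a.info_scores is not None and vid in a_col:
                info[jo] = a.info_scores[a_col[vid]]
            elif b.info_scores is not None and vid in b_col:
                info[jo] = b.info_scores[b_col[vid]]

    ids_b = b.sample_ids
    if dup:
        ids_b = [f"{s}_{cohort_names[1]}" if s in dup else s for s in ids_b]
    sample_ids = list(a.sample_ids) + list(ids_b)

    pheno = None
    tables = []
    if a.phenotable is not None:
        ta = a.phenotable.loc[a.sample_ids].copy()
        ta["cohort"] = cohort_names[0]
        tables.append(ta)
    if b.phenotable is not None:
        tb = b.phenotable.loc[b.sample_ids].copy()
        tb.index = ids_b
        tb["cohort"] = cohort_names[1]
        tables.append(tb)
    if tables:
        pheno = pd.concat(tables)
        pheno = pheno.reindex(sample_ids)

    merged = GenotypeDataset(sample_ids, variants, out, pheno, info)
    # sort by genomic coordinate so neighbor-based imputation is valid
    order = np.lexsort((merged.variants["pos"].to_numpy(), _chrom_sort_key(merged.variants["chrom"])))
    return merged.take_variants(order)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_regression(
    dataset: GenotypeDataset,
    window_snps: int = 10,
    r2_min: float = 0.8,
    max_rounds: int = 10,
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Fill missing calls by linear regression on neighboring complete SNPs.

    For each variant with missing entries, the ``window_snps`` nearest
    fully-observed variants on the same chromosome (by base-pair distance)
    serve as predictors. An OLS fit on the samples where the target is
    observed is accepted if its in-sample R^2 >= ``r2_min``; predictions are
    rounded to the nearest of {0, 1, 2}. Whole passes repeat until no entry
    changes or ``max_rounds`` is reached (columns completed in one pass can
    serve as predictors in the next). Returns the imputed dataset and a
    per-round report of filled-call counts.
    """
    v = dataset.variants
    order = np.lexsort((v["pos"].to_numpy(), _chrom_sort_key(v["chrom"])))
    if not np.array_equal(order, np.arange(len(v))):
        raise ValueError("variants must be sorted by (chrom, pos); merge_datasets output is")

    d = dataset.dosages.astype(np.float64)
    d[d == MISSING] = np.nan
    chrom = v["chrom"].to_numpy(str)
    pos = v["pos"].to_numpy()
    report_rows = []

    for rnd in range(1, max_rounds + 1):
        complete = ~np.isnan(d).any(axis=0)
        targets = np.flatnonzero(np.isnan(d).any(axis=0))
        n_filled = 0
        for j in targets:
            same = np.flatnonzero(complete & (chrom == chrom[j]))
            if same.size == 0:
                continue
            nb = same[np.argsort(np.abs(pos[same] - pos[j]), kind="stable")][:window_snps]
            obs = ~np.isnan(d[:, j])
            if obs.sum() <= nb.size + 1:
                continue
            X = np.column_stack([np.ones(int(obs.sum())), d[obs][:, nb]])
            y = d[obs, j]
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            fitted = X @ coef
            ss_res = float(np.sum((y - fitted) ** 2))
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            if ss_tot <= 0:
                r2 = 1.0  # constant observed column: trivially predictable
            else:
                r2 = 1.0 - ss_res / ss_tot
            if r2 >= r2_min:
                rows = np.flatnonzero(~obs)
                Xm = np.column_stack([np.ones(rows.size), d[rows][:, nb]])
                pred = np.clip(np.rint(Xm @ coef), 0, 2)
                d[rows, j] = pred
                n_filled += rows.size
        report_rows.append((rnd, n_filled))
        if n_filled == 0:
            break

    out = d.copy()
    out[np.isnan(out)] = MISSING
    imputed = GenotypeDataset(
        dataset.sample_ids, dataset.variants, out.astype(np.int8), dataset.phenotable, dataset.info_scores
    )
    report = pd.DataFrame(report_rows, columns=["round", "n_imputed"])
    return imputed, report


def knn_distances(dosages: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Pairwise sample distance: mean |dosage difference| over mutually
    observed variants (nan when two samples share no observed variant)."""
    X = dosages.astype(np.float64)
    X[X == MISSING] = np.nan
    n = X.shape[0]
    D = np.empty((n, n))
    obs = ~np.isnan(X)
    Xz = np.nan_to_num(X)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        diff = np.abs(Xz[start:stop, None, :] - Xz[None, :, :])
        both = obs[start:stop, None, :] & obs[None, :, :]
        cnt = both.sum(axis=2)
        with np.errstate(invalid="ignore"):
            D[start:stop] = np.where(cnt > 0, (diff * both).sum(axis=2) / cnt, np.nan)
    return D


def _modal(values: np.ndarray) -> int:
    """Modal dosage; ties broken toward the smaller dosage."""
    counts = np.bincount(values.astype(int), minlength=3)
    return int(np.argmax(counts))


def impute_knn(dataset: GenotypeDataset, k: int = 10) -> GenotypeDataset:
    """Fill all remaining missing calls with the modal dosage of the k
    nearest samples observed at that variant.

    Distance is the mean absolute dosage difference over mutually observed
    variants. A sample sharing no observed variant with any other sample
    falls back to per-variant cohort modal dosage (with a warning), as does
    a variant observed in no neighbor.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = dataset.dosages.copy()
    if not (d == MISSING).any():
        return dataset.copy()
    D = knn_distances(d)
    np.fill_diagonal(D, np.inf)
    n = d.shape[0]

    # cohort modal dosage per variant (over observed calls)
    col_modal = np.zeros(d.shape[1], dtype=np.int8)
    for j in range(d.shape[1]):
        obs = d[:, j] != MISSING
        col_modal[j] = _modal(d[obs, j]) if obs.any() else 0

    for i in range(n):
        miss = np.flatnonzero(d[i] == MISSING)
        if miss.size == 0:
            continue
        dist = D[i].copy()
        if np.isnan(dist).all() or not np.isfinite(np.nanmin(dist)):
            warnings.warn(f"sample {dataset.sample_ids[i]} shares no observed variant with any other; using cohort modal dosages")
            d[i, miss] = col_modal[miss]
            continue
        dist[np.isnan(dist)] = np.inf
        ranked = np.argsort(dist, kind="stable")
        ranked = ranked[np.isfinite(dist[ranked])]
        source = dataset.dosages  # donate observed calls only, never imputed ones
        for j in miss:
            donors = []
            for s in ranked:
                if source[s, j] != MISSING:
                    donors.append(source[s, j])
                    if len(donors) == k:
                        break
            d[i, j] = _modal(np.asarray(donors)) if donors else col_modal[j]
    return GenotypeDataset(dataset.sample_ids, dataset.variants, d, dataset.phenotable, dataset.info_scores)


def apply_allele_authority(
    a: GenotypeDataset,
    b: GenotypeDataset,
    plan: MergePlan,
    risk_allele: Mapping[str, str],
) -> MergePlan:
    """Rescue drop-class shared variants using an offline risk-allele map.

    For a dropped shared variant whose mapped risk allele appears in both
    cohorts' allele pairs (directly or as a strand image), reclassify it so
    both cohorts count the mapped allele; variants the map cannot resolve
    stay dropped.
    """
    va = a.variants.set_index("id")
    vb = b.variants.set_index("id")
    still_dropped = []
    for vid in plan.drop:
        risk = risk_allele.get(vid)
        resolved = False
        if risk is not None and vid in va.index and vid in vb.index:
            a1, a2 = str(va.loc[vid, "allele1"]), str(va.loc[vid, "allele2"])
            b1, b2 = str(vb.loc[vid, "allele1"]), str(vb.loc[vid, "allele2"])
            if not is_palindromic(a1, a2) and not is_palindromic(b1, b2):
                def orient(x1: str, x2: str) -> str | None:
                    if risk in (x1,):
                        return "as_is"
                    if risk in (x2,):
                        return "switch"
                    if risk == COMPLEMENT.get(x1):
                        return "as_is"
                    if risk == COMPLEMENT.get(x2):
                        return "switch"
                    return None

                oa, ob = orient(a1, a2), orient(b1, b2)
                if oa == "as_is" and ob is not None:
                    resolved = True
                    if ob == "as_is":
                        plan.identical.append(vid)
                    else:
                        plan.switch.append(vid)
        if not resolved:
            still_dropped.append(vid)
    plan.drop = still_dropped
    plan.validate()
    return plan
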