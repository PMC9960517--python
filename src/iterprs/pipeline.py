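"""Iterative PRS derivation, aggregation, penalized selection and evaluation.

The stabilization procedure:

1. **Iterate** (default 100x): split samples 80/20 into source (training)
   and target (testing) sets; recompute PCs and their Tracy-Widom count on
   the training set; derive per-SNP summary statistics on the training set
   with each engine; run a clumping+thresholding search on the test set.
   Each iteration's best test-set PRS R^2 per engine forms that engine's
   *baseline distribution*.
2. **Select an engine** by mean per-iteration PRS R^2.
3. **Aggregate**: count how often each variant appears in the selected
   engine's per-iteration models; keep variants appearing at least
   ``min_freq`` times (default 5), weight = mean beta over the iterations
   where the variant appears.
4. **Scan candidates**: for every observed appearance frequency f, the
   variants with count >= f form a candidate score, evaluated on the stored
   per-iteration test splits; mean R^2 is penalized as R^2 / log(N SNPs).
5. **Select**: each candidate carries an empirical bootstrap p-value (the
   fraction of baseline R^2 values exceeding its mean R^2); candidates that
   do not maintain significance against the baseline are set aside, and
   among the rest the local maximum of the penalized curve with the highest
   value wins (ties -> fewer SNPs).
6. **Evaluate** the final model on leave-out fractions 5%..50% and on the
   whole dataset.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .assoc import DEFAULT_COVARIATES, compare_engines, summary_stats
from .genio import GenotypeDataset
from .scoring import DEFAULT_THRESHOLDS, PRSFit, PRSModel, compute_prs, ct_search, prs_r2
from .strat import pca_with_selection

__all__ = [
    "IterationResult",
    "CandidateScore",
    "PipelineOutcome",
    "run_iterations",
    "aggregate_snps",
    "candidate_scan",
    "penalize",
    "find_local_maxima",
    "select_final",
    "bootstrap_p",
    "evaluate_final",
    "run_pipeline",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class IterationResult:
    """One train/test split's derivation outcome."""

    index: int
    train_ids: list[str]
    test_ids: list[str]
    models: dict[str, PRSModel]  # engine -> chosen model
    fits: dict[str, PRSFit]  # engine -> test-set fit
    n_pcs_train: int
    test_pcs: np.ndarray  # stored for candidate evaluation re-use

    def validate(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


@dataclasses.dataclass
class CandidateScore:
    """One frequency-threshold candidate of the aggregated scan."""

    freq_threshold: int
    n_snps: int
    mean_r2: float
    sd_r2: float
    penalized_r2: float
    boot_p: float
    model: PRSModel


@dataclasses.dataclass
class PipelineOutcome:
    """Bundle of everything the iterative pipeline produces."""

    iterations: list[IterationResult]
    baselines: dict[str, np.ndarray]
    engine_table: pd.DataFrame
    selected_engine: str
    freq_table: pd.DataFrame
    candidates: list[CandidateScore]
    final_model: PRSModel
    final_candidate: CandidateScore
    evaluation: pd.DataFrame | None = None

    def candidate_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.freq_threshold, c.n_snps, c.mean_r2, c.sd_r2, c.penalized_r2, c.boot_p)
                for c in self.candidates
            ],
            columns=["freq_threshold", "n_snps", "mean_r2", "sd_r2", "penalized_r2", "boot_p"],
        )


# ---------------------------------------------------------------------------
# Stage 1: iterations
# ---------------------------------------------------------------------------

def run_iterations(
    dataset: GenotypeDataset,
    n_iter: int = 100,
    train_frac: float = 0.8,
    engines: Sequence[str] = ("wald_ols", "score_test"),
    master_seed: int = 0,
    phenotype_name: str = "phenotype",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    max_pcs: int = 20,
    tw_alpha: float = 0.05,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    clump_r2: float = 0.1,
    clump_window_kb: float = 250.0,
    pca_mode: str = "per_split",
) -> tuple[list[IterationResult], dict[str, np.ndarray]]:
    """Repeat split -> train-set association -> test-set C+T search.

    Returns the per-iteration results and, per engine, the baseline
    distribution of test-set PRS R^2 values. Deterministic given
    ``master_seed``.
    """
    n = dataset.n_samples
    n_train = int(round(train_frac * n))
    if n_train < 10 or n - n_train < 10:
        raise ValueError(f"dataset too small for a {train_frac:.0%} split: n={n}")
    if pca_mode not in ("per_split", "global"):
        raise ValueError("pca_mode must be 'per_split' or 'global'")

    global_pca = None
    if pca_mode == "global":
        global_pca = pca_with_selection(dataset, n_components=max_pcs, alpha=tw_alpha)

    results: list[IterationResult] = []
    baselines: dict[str, list[float]] = {e: [] for e in engines}
    for it in range(n_iter):
        rng = substream(master_seed, "split", it)
        perm = rng.permutation(n)
        train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        train = dataset.take_samples(train_idx)
        test = dataset.take_samples(test_idx)

        if pca_mode == "per_split":
            p_train = pca_with_selection(train, n_components=max_pcs, alpha=tw_alpha)
            train_pcs = p_train.selected_scores()
            n_pcs_train = p_train.n_selected or 0
            p_test = pca_with_selection(test, n_components=max_pcs, alpha=tw_alpha)
            test_pcs = p_test.selected_scores()
        else:
            train_pcs = global_pca.selected_scores()[train_idx]
            n_pcs_train = global_pca.n_selected or 0
            test_pcs = global_pca.selected_scores()[test_idx]

        models: dict[str, PRSModel] = {}
        fits: dict[str, PRSFit] = {}
        for engine in engines:
            ss = summary_stats(
                train, phenotype_name=phenotype_name, covariates=covariates,
                pcs=train_pcs, engine=engine,
            )
            model, fit = ct_search(
                ss, test, thresholds=thresholds, phenotype_name=phenotype_name,
                covariates=covariates, pcs=test_pcs, r2_max=clump_r2,
                window_kb=clump_window_kb,
            )
            models[engine] = model
            fits[engine] = fit
            baselines[engine].append(fit.prs_r2)

        res = IterationResult(
            index=it,
            train_ids=[dataset.sample_ids[i] for i in train_idx],
            test_ids=[dataset.sample_ids[i] for i in test_idx],
            models=models,
            fits=fits,
            n_pcs_train=n_pcs_train,
            test_pcs=np.asarray(test_pcs),
        )
        res.validate()
        results.append(res)
        log.info(
            "iteration %d: %s", it,
            ", ".join(f"{e}: R2={fits[e].prs_r2:.4f} n_snps={fits[e].n_snps}" for e in engines),
        )
    return results, {e: np.asarray(v) for e, v in baselines.items()}


# ---------------------------------------------------------------------------
# Stage 2-3: engine choice and aggregation
# ---------------------------------------------------------------------------

def aggregate_snps(
    results: Sequence[IterationResult], engine: str, min_freq: int = 5
) -> pd.DataFrame:
    """Count appearances of each variant in the engine's per-iteration
    models and average its beta over the iterations where it appears.

    Variants appearing fewer than ``min_freq`` times are dropped. Returns a
    DataFrame (id, effect_allele, count, mean_beta) sorted by descending
    count then id.
    """
    if not results:
        raise ValueError("no iteration results to aggregate")
    counts: dict[str, int] = {}
    sums: dict[str, float] = {}
    alleles: dict[str, str] = {}
    any_entries = False
    for res in results:
        model = res.models.get(engine)
        if model is None:
            raise ValueError(f"iteration {res.index} has no model for engine {engine!r}")
        if model.n_snps:
            any_entries = True
        for row in model.entries.itertuples(index=False):
            counts[row.id] = counts.get(row.id, 0) + 1
            sums[row.id] = sums.get(row.id, 0.0) + float(row.weight)
            alleles.setdefault(row.id, str(row.effect_allele))
    if not any_entries:
        raise ValueError("all per-iteration models are empty")
    rows = [
        (vid, alleles[vid], c, sums[vid] / c)
        for vid, c in counts.items()
        if c >= min_freq
    ]
    table = pd.DataFrame(rows, columns=["id", "effect_allele", "count", "mean_beta"])
    return table.sort_values(["count", "id"], ascending=[False, True], kind="stable").reset_index(drop=True)


def penalize(r2: float, n_snps: int, log_base: float = math.e) -> float:
    """Size-penalized PRS R^2: r2 / log_base(n_snps). Requires n_snps >= 2."""
    if n_snps < 2:
        raise ValueError("penalization needs n_snps >= 2 (log must be positive)")
    if log_base <= 1:
        raise ValueError("log_base must exceed 1")
    return r2 / (math.log(n_snps) / math.log(log_base))


def candidate_scan(
    freq_table: pd.DataFrame,
    dataset: GenotypeDataset,
    results: Sequence[IterationResult],
    baseline: np.ndarray,
    phenotype_name: str = "phenotype",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    denominator_mode: str = "allele_count",
    log_base: float = math.e,
) -> list[CandidateScore]:
    """Evaluate one aggregated candidate per observed appearance frequency.

    For each distinct frequency f in the table, the candidate holds the
    variants with count >= f, weighted by mean beta, and is scored on every
    stored test split (reusing each split's stored PCs as covariates).
    Candidates are returned ordered by ascending n_snps (descending f).
    """
    if freq_table.empty:
        raise ValueError("empty frequency table")
    pos = {s: i for i, s in enumerate(dataset.sample_ids)}
    tab = dataset.phenotable.loc[dataset.sample_ids]
    y_all = tab[phenotype_name].to_numpy(float)
    C_all = np.column_stack([tab[c].to_numpy(float) for c in covariates]) if covariates else None

    candidates: list[CandidateScore] = []
    for f in sorted(freq_table["count"].unique(), reverse=True):
        sel = freq_table[freq_table["count"] >= f]
        entries = pd.DataFrame(
            {"id": sel["id"].to_numpy(), "effect_allele": sel["effect_allele"].to_numpy(),
             "weight": sel["mean_beta"].to_numpy(float)}
        )
        model = PRSModel(entries, denominator_mode=denominator_mode,
                         provenance={"freq_threshold": int(f)})
        scores = compute_prs(dataset, model)
        r2s = []
        for res in results:
            idx = np.asarray([pos[s] for s in res.test_ids])
            C = C_all[idx] if C_all is not None else None
            if res.test_pcs.size:
                C = res.test_pcs if C is None else np.hstack([C, res.test_pcs])
            fit = prs_r2(scores[idx], y_all[idx], C, n_snps=model.n_snps)
            r2s.append(fit.prs_r2)
        r2s = np.asarray(r2s)
        mean_r2 = float(r2s.mean())
        pen = penalize(mean_r2, model.n_snps, log_base) if model.n_snps >= 2 else mean_r2
        candidates.append(
            CandidateScore(
                freq_threshold=int(f),
                n_snps=model.n_snps,
                mean_r2=mean_r2,
                sd_r2=float(r2s.std(ddof=1)) if r2s.size > 1 else 0.0,
                penalized_r2=pen,
                boot_p=bootstrap_p(baseline, mean_r2),
                model=model,
            )
        )
    candidates.sort(key=lambda c: (c.n_snps, -c.freq_threshold))
    return candidates


def find_local_maxima(candidates: Sequence[CandidateScore]) -> list[CandidateScore]:
    """Candidates whose penalized R^2 is >= both neighbors in n_snps order.

    Endpoints are compared to their single neighbor; for a plateau only its
    first (smallest-n_snps) candidate is reported.
    """
    if not candidates:
        raise ValueError("no candidates")
    vals = [c.penalized_r2 for c in candidates]
    k = len(vals)
    out = []
    for i, c in enumerate(candidates):
        left_ok = i == 0 or vals[i] >= vals[i - 1]
        right_ok = i == k - 1 or vals[i] >= vals[i + 1]
        on_plateau_tail = i > 0 and vals[i] == vals[i - 1]
        if left_ok and right_ok and not on_plateau_tail:
            out.append(c)
    return out


def select_final(
    candidates: Sequence[CandidateScore], select_alpha: float = 0.05
) -> tuple[PRSModel, CandidateScore]:
    """Pick the best candidate: high penalized R^2 while maintaining
    significance against the baseline distribution.

    Candidates whose empirical bootstrap p exceeds ``select_alpha`` are set
    aside first (a high-penalized-R^2 score that a single unaggregated
    iteration regularly beats is not an improvement); if no candidate
    qualifies, those attaining the minimum observed bootstrap p are kept
    instead. Among the kept candidates the local maxima of the penalized
    curve are detected and the highest penalized R^2 wins; ties resolve
    toward fewer SNPs.
    """
    if not candidates:
        raise ValueError("no candidates")
    kept = [c for c in candidates if c.boot_p <= select_alpha]
    if not kept:
        p_min = min(c.boot_p for c in candidates)
        kept = [c for c in candidates if c.boot_p == p_min]
    maxima = find_local_maxima(kept)
    best = max(maxima, key=lambda c: (c.penalized_r2, -c.n_snps))
    return best.model, best


def bootstrap_p(baseline: np.ndarray, aggregated_r2: float) -> float:
    """Empirical bootstrap p: fraction of baseline R^2 values strictly
    greater than the aggregated PRS R^2."""
    b = np.asarray(baseline, float)
    if b.size == 0:
        raise ValueError("empty baseline distribution")
    return float(np.count_nonzero(b > aggregated_r2)) / b.size


# ---------------------------------------------------------------------------
# Stage 4: evaluation
# ---------------------------------------------------------------------------

def evaluate_final(
    dataset: GenotypeDataset,
    model: PRSModel,
    leftout_fracs: Sequence[float] = tuple(np.round(np.arange(0.05, 0.51, 0.05), 2)),
    reps_per_frac: int = 10,
    phenotype_name: str = "phenotype",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    max_pcs: int = 20,
    tw_alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-out evaluation of the final model.

    For each left-out fraction, ``reps_per_frac`` random holdouts are drawn;
    the full (covariates + PRS) and reduced (covariates) models are fitted
    on the retained samples and the incremental R^2 recorded. A final row
    (frac = 0) reports the whole-dataset fit. PCs are computed once on the
    full dataset and subset per holdout.
    """
    if model.n_snps < 1:
        raise ValueError("empty PRS model")
    fracs = [float(f) for f in leftout_fracs]
    if any(not 0.0 < f <= 0.5 for f in fracs):
        raise ValueError("left-out fractions must lie in (0, 0.5]")

    tab = dataset.phenotable.loc[dataset.sample_ids]
    y = tab[phenotype_name].to_numpy(float)
    C = np.column_stack([tab[c].to_numpy(float) for c in covariates]) if covariates else None
    pcs = pca_with_selection(dataset, n_components=max_pcs, alpha=tw_alpha).selected_scores()
    if pcs.size:
        C = pcs if C is None else np.hstack([C, pcs])
    scores = compute_prs(dataset, model)
    n = dataset.n_samples

    rows = []
    for frac in fracs:
        n_out = int(round(frac * n))
        r2s, ps = [], []
        for rep in range(reps_per_frac):
            rng = substream(seed, "evaluate", int(round(frac * 100)), rep)
            keep = np.sort(rng.permutation(n)[n_out:])
            fit = prs_r2(scores[keep], y[keep], None if C is None else C[keep], n_snps=model.n_snps)
            r2s.append(fit.prs_r2)
            ps.append(fit.p_value)
        rows.append(
            (frac, n - n_out, float(np.mean(r2s)),
             float(np.std(r2s, ddof=1)) if len(r2s) > 1 else 0.0, float(np.median(ps)))
        )
    whole = prs_r2(scores, y, C, n_snps=model.n_snps)
    rows.append((0.0, n, whole.prs_r2, 0.0, whole.p_value))
    return pd.DataFrame(rows, columns=["leftout_frac", "n_retained", "mean_r2", "sd_r2", "median_p"])


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(
    dataset: GenotypeDataset,
    n_iter: int = 100,
    train_frac: float = 0.8,
    engines: Sequence[str] = ("wald_ols", "score_test"),
    master_seed: int = 0,
    min_freq: int = 5,
    phenotype_name: str = "phenotype",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    max_pcs: int = 20,
    tw_alpha: float = 0.05,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    clump_r2: float = 0.1,
    clump_window_kb: float = 250.0,
    pca_mode: str = "per_split",
    log_base: float = math.e,
    select_alpha: float = 0.05,
    evaluate: bool = True,
    reps_per_frac: int = 10,
) -> PipelineOutcome:
    """Run the full iterative-aggregation pipeline on a QC'd dataset."""
    results, baselines = run_iterations(
        dataset, n_iter=n_iter, train_frac=train_frac, engines=engines,
        master_seed=master_seed, phenotype_name=phenotype_name,
        covariates=covariates, max_pcs=max_pcs, tw_alpha=tw_alpha,
        thresholds=thresholds, clump_r2=clump_r2,
        clump_window_kb=clump_window_kb, pca_mode=pca_mode,
    )
    engine_table = compare_engines({e: list(v) for e, v in baselines.items()})
    selected_engine = str(engine_table.loc[engine_table["selected"], "engine"].iloc[0])
    log.info("selected engine: %s", selected_engine)

    freq_table = aggregate_snps(results, selected_engine, min_freq=min_freq)
    if freq_table.empty:
        raise ValueError(f"no variant appears at least {min_freq} times; nothing to aggregate")
    candidates = candidate_scan(
        freq_table, dataset, results, baselines[selected_engine],
        phenotype_name=phenotype_name, covariates=covariates, log_base=log_base,
    )
    final_model, final_candidate = select_final(candidates, select_alpha=select_alpha)
    log.info(
        "final PRS: %d SNPs (freq >= %d), mean R2 %.4f, penalized %.4f, bootstrap p %.3f",
        final_candidate.n_snps, final_candidate.freq_threshold,
        final_candidate.mean_r2, final_candidate.penalized_r2, final_candidate.boot_p,
    )

    evaluation = None
    if evaluate:
        evaluation = evaluate_final(
            dataset, final_model, phenotype_name=phenotype_name, covariates=covariates,
            max_pcs=max_pcs, tw_alpha=tw_alpha, seed=master_seed, reps_per_frac=reps_per_frac,
        )
    return PipelineOutcome(
        iterations=results,
        baselines=baselines,
        engine_table=engine_table,
        selected_engine=selected_engine,
        freq_table=freq_table,
        candidates=candidates,
        final_model=final_model,
        final_candidate=final_candidate,
        evaluation=evaluation,
    )
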