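"""Variant and sample quality control.

Filters follow standard array-QC practice: imputation INFO score >= 0.9,
SNP call rate >= 95%, MAF >= 5%, sample call rate >= 90%, and — in a second
round on the surviving genotypes — an exact Hardy-Weinberg equilibrium test
at p >= 1e-9. The HWE test is the exact conditional enumeration (Wigginton
et al. style) rather than the chi-square approximation, which is unreliable
in the extreme tail the 1e-9 cutoff lives in.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeDataset

__all__ = [
    "QCReport",
    "hwe_exact_p",
    "hwe_pvalues",
    "filter_variants",
    "filter_samples",
    "drop_incomplete_covariates",
]


@dataclasses.dataclass
class QCReport:
    """Accounting for one filtering pass."""

    n_variants_in: int
    n_variants_out: int
    n_samples_in: int
    n_samples_out: int
    removed: dict[str, int]
    thresholds: dict[str, float]

    def validate(self) -> None:
        if any(v < 0 for v in self.removed.values()):
            raise ValueError("negative removal count")
        n_removed = sum(self.removed.values())
        ok_v = self.n_variants_in - n_removed == self.n_variants_out
        ok_s = self.n_samples_in - n_removed == self.n_samples_out
        if not (ok_v or ok_s):
            raise ValueError("in - removed != out on both axes")

    def to_frame(self) -> pd.DataFrame:
        rows = [("n_variants_in", self.n_variants_in), ("n_variants_out", self.n_variants_out),
                ("n_samples_in", self.n_samples_in), ("n_samples_out", self.n_samples_out)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows += [(f"threshold_{k}", v) for k, v in self.thresholds.items()]
        return pd.DataFrame(rows, columns=["key", "value"])


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts (same parity) whose conditional probability does
    not exceed the observed one. Uses the standard recurrence on the
    conditional distribution, in log space for stability.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("at least one genotype must be observed")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het  # minor allele count
    if n_rare == 0:
        return 1.0

    # het counts share the parity of the minor-allele count
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    # unnormalized log P(het = h | n, n_rare) via the pmf recurrence
    #   P(h+2) / P(h) = 4 * hom_rare(h) * hom_common(h) / ((h+2)(h+1))
    # with hom_rare(h) = (n_rare - h)/2 and hom_common(h) = n - h - hom_rare(h)
    logp = np.zeros(het_values.size)
    for i in range(1, het_values.size):
        h = het_values[i - 1]
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        ratio = 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        logp[i] = logp[i - 1] + np.log(ratio)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[het_values == n_het][0]
    return float(np.minimum(p[p <= p_obs * (1.0 + 1e-12)].sum(), 1.0))


def hwe_pvalues(dataset: GenotypeDataset) -> np.ndarray:
    """Exact HWE p per variant, computed from non-missing calls."""
    out = np.ones(dataset.n_variants)
    d = dataset.dosages
    for j in range(dataset.n_variants):
        col = d[:, j]
        obs = col != MISSING
        if not obs.any():
            continue
        n2 = int((col[obs] == 2).sum())
        n1 = int((col[obs] == 1).sum())
        n0 = int((col[obs] == 0).sum())
        out[j] = hwe_exact_p(n2, n1, n0)
    return out


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def filter_variants(
    dataset: GenotypeDataset,
    info_min: float = 0.9,
    call_min: float = 0.95,
    maf_min: float = 0.05,
    hwe_min: float = 1e-9,
    known_ids: Sequence[str] | None = None,
) -> tuple[GenotypeDataset, QCReport]:
    """Drop variants failing INFO / call-rate / MAF / HWE thresholds.

    Filters apply in order (a variant is counted under the first filter it
    fails): INFO (skipped when the dataset has no INFO scores), call rate,
    MAF, then exact HWE on the variants that survived the first round.
    ``known_ids``, when given, restricts the analysis to that id universe
    first (e.g. an offline stand-in for a known-variant registry).
    """
    for name, v in (("info_min", info_min), ("call_min", call_min), ("maf_min", maf_min), ("hwe_min", hwe_min)):
        _check_unit(name, v)

    m = dataset.n_variants
    removed = {"unknown_id": 0, "info": 0, "call_rate": 0, "maf": 0, "hwe": 0}
    keep = np.ones(m, dtype=bool)

    if known_ids is not None:
        known = dataset.variants["id"].isin(set(known_ids)).to_numpy()
        removed["unknown_id"] = int((~known).sum())
        keep &= known

    if dataset.info_scores is not None:
        fail = keep & (np.nan_to_num(dataset.info_scores, nan=0.0) < info_min)
        removed["info"] = int(fail.sum())
        keep &= ~fail

    call = dataset.variant_call_rate()
    fail = keep & (call < call_min)
    removed["call_rate"] = int(fail.sum())
    keep &= ~fail

    maf = np.nan_to_num(dataset.maf(), nan=0.0)
    fail = keep & (maf < maf_min)
    removed["maf"] = int(fail.sum())
    keep &= ~fail

    # second round: exact HWE on survivors
    survivors = dataset.take_variants(np.flatnonzero(keep))
    hwe = hwe_pvalues(survivors)
    fail_h = hwe < hwe_min
    removed["hwe"] = int(fail_h.sum())
    out = survivors.take_variants(np.flatnonzero(~fail_h))

    report = QCReport(
        n_variants_in=m,
        n_variants_out=out.n_variants,
        n_samples_in=dataset.n_samples,
        n_samples_out=dataset.n_samples,
        removed=removed,
        thresholds={"info_min": info_min, "call_min": call_min, "maf_min": maf_min, "hwe_min": hwe_min},
    )
    report.validate()
    return out, report


def filter_samples(dataset: GenotypeDataset, call_min: float = 0.90) -> tuple[GenotypeDataset, QCReport]:
    """Drop samples whose call rate falls below ``call_min``."""
    _check_unit("call_min", call_min)
    call = dataset.sample_call_rate()
    keep = call >= call_min
    out = dataset.take_samples(np.flatnonzero(keep))
    report = QCReport(
        n_variants_in=dataset.n_variants,
        n_variants_out=dataset.n_variants,
        n_samples_in=dataset.n_samples,
        n_samples_out=out.n_samples,
        removed={"sample_call_rate": int((~keep).sum())},
        thresholds={"call_min": call_min},
    )
    report.validate()
    return out, report


def drop_incomplete_covariates(
    dataset: GenotypeDataset, required_covariates: Sequence[str]
) -> tuple[GenotypeDataset, QCReport]:
    """Drop samples with any missing value among the required covariates."""
    if dataset.phenotable is None:
        raise ValueError("dataset has no phenotype table")
    missing_cols = [c for c in required_covariates if c not in dataset.phenotable.columns]
    if missing_cols:
        raise ValueError(f"phenotable lacks required covariates: {missing_cols}")
    table = dataset.phenotable.loc[dataset.sample_ids, list(required_covariates)]
    keep = ~table.isna().any(axis=1).to_numpy()
    out = dataset.take_samples(np.flatnonzero(keep))
    report = QCReport(
        n_variants_in=dataset.n_variants,
        n_variants_out=dataset.n_variants,
        n_samples_in=dataset.n_samples,
        n_samples_out=out.n_samples,
        removed={"incomplete_covariates": int((~keep).sum())},
        thresholds={},
    )
    report.validate()
    return out, report
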