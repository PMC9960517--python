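"""Population-stratification PCA and Tracy-Widom PC selection.

Dosage columns are centered and scaled by sqrt(p(1-p)) (p = allele
frequency), the normalization under which the eigenvalues of the
sample-by-sample covariance follow Tracy-Widom theory in the null case.
The number of significant axes of variation is chosen by sequentially
testing leading eigenvalues against the TW1 distribution with the
moment-based effective-marker-count estimator (Patterson-style): at each
step the remaining spectrum's first two moments give an effective marker
count n_hat, the top eigenvalue is centered/scaled to the TW variable and
compared to the critical value at ``alpha``; testing stops at the first
non-significant eigenvalue.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .genio import MISSING, GenotypeDataset

__all__ = ["PCAResult", "pca", "tracy_widom_select", "tw1_critical", "TW1_QUANTILES"]

#: upper-tail probability -> TW1 critical value. The 0.05 / 0.01 / 0.001
#: entries are the classical published thresholds (0.9793 / 2.0234 / 3.2724);
#: the rest of the grid was derived once from the Chiani (2014) shifted-gamma
#: approximation of TW1 (k=46.446, theta=0.18605, shift 9.84801), which
#: reproduces the classical entries to ~0.03.
TW1_QUANTILES: tuple[tuple[float, float], ...] = (
    (0.5, -1.2685),
    (0.2, -0.1614),
    (0.1, 0.4531),
    (0.05, 0.9793),
    (0.025, 1.4499),
    (0.01, 2.0234),
    (0.005, 2.4224),
    (0.001, 3.2724),
    (1e-4, 4.3212),
    (1e-5, 5.2985),
)


def tw1_critical(alpha: float) -> float:
    """Critical value of the Tracy-Widom (beta=1) statistic at upper-tail
    probability ``alpha``, by log-linear interpolation of a static table."""
    probs = np.array([p for p, _ in TW1_QUANTILES])
    crits = np.array([c for _, c in TW1_QUANTILES])
    if not probs[-1] <= alpha <= probs[0]:
        raise ValueError(f"alpha must be in [{probs[-1]}, {probs[0]}], got {alpha}")
    # table is stored with decreasing alpha; np.interp needs ascending x
    return float(np.interp(np.log(alpha), np.log(probs[::-1]), crits[::-1]))


@dataclasses.dataclass
class PCAResult:
    """Spectrum and scores of the standardized-dosage PCA."""

    eigenvalues: np.ndarray  # full spectrum, descending
    scores: np.ndarray  # n_samples x n_components
    n_samples: int
    n_variants_used: int
    n_selected: int | None = None

    def selected_scores(self) -> np.ndarray:
        k = self.n_selected if self.n_selected is not None else self.scores.shape[1]
        return self.scores[:, :k]


def pca(dataset: GenotypeDataset, n_components: int = 20, dtype=np.float32) -> PCAResult:
    """PCA of the column-standardized dosage matrix.

    Columns are centered at 2p and scaled by sqrt(p(1-p)); monomorphic
    columns are skipped. The full eigenvalue spectrum of the sample-by-
    sample covariance is returned (needed by the Tracy-Widom test) along
    with the top ``n_components`` score vectors. The Gram matrix is
    accumulated in float32 by default; eigendecomposition runs in float64.
    """
    if (dataset.dosages == MISSING).any():
        raise ValueError("PCA requires complete dosages; run imputation first")
    d = dataset.dosages.astype(dtype)
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    d = d[:, poly]
    p = p[poly]
    m_used = int(poly.sum())
    if m_used == 0:
        raise ValueError("no polymorphic variants available for PCA")
    X = (d - 2.0 * p) / np.sqrt(p * (1.0 - p))
    gram = (X @ X.T).astype(np.float64) / m_used
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    k = min(n_components, len(evals))
    scores = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0) * m_used)
    return PCAResult(eigenvalues=evals, scores=scores, n_samples=dataset.n_samples, n_variants_used=m_used)


def tracy_widom_select(
    eigenvalues: np.ndarray,
    n_samples: int,
    n_variants: int,
    alpha: float = 0.05,
    max_select: int | None = None,
) -> int:
    """Count significant PCs by sequential Tracy-Widom testing.

    At step k the remaining eigenvalues (after removing the k already
    accepted) define an effective marker count

        n_hat = (m' + 1) S1^2 / ((m' - 1) S2 - S1^2),

    the leading remaining eigenvalue is normalized to l = m' lambda / S1 and
    centered/scaled with mu = (sqrt(n_hat-1) + sqrt(m'))^2 / n_hat and the
    matching TW sigma; testing stops at the first statistic below the
    critical value at ``alpha``.
    """
    lam = np.asarray(eigenvalues, float)
    lam = lam[lam > 1e-10]
    if lam.size < 2:
        raise ValueError("need at least 2 positive eigenvalues")
    lam = np.sort(lam)[::-1]
    crit = tw1_critical(alpha)
    limit = lam.size - 1 if max_select is None else min(max_select, lam.size - 1)

    n_selected = 0
    for k in range(limit):
        rest = lam[k:]
        mprime = rest.size
        s1 = float(rest.sum())
        s2 = float((rest**2).sum())
        denom = (mprime - 1) * s2 - s1**2
        if denom <= 0:
            break  # spectrum flatter than any random matrix: nothing significant
        n_hat = (mprime + 1) * s1**2 / denom
        if n_hat <= 1:
            break
        ell = mprime * rest[0] / s1
        sq = np.sqrt(n_hat - 1) + np.sqrt(mprime)
        mu = sq**2 / n_hat
        sigma = (sq / n_hat) * (1.0 / np.sqrt(n_hat - 1) + 1.0 / np.sqrt(mprime)) ** (1.0 / 3.0)
        x = (ell - mu) / sigma
        if x > crit:
            n_selected += 1
        else:
            break
    return n_selected


def pca_with_selection(
    dataset: GenotypeDataset, n_components: int = 20, alpha: float = 0.05
) -> PCAResult:
    """Convenience wrapper: PCA plus Tracy-Widom selection, capped at
    ``n_components`` selected PCs."""
    res = pca(dataset, n_components=n_components)
    res.n_selected = min(
        tracy_widom_select(res.eigenvalues, res.n_samples, res.n_variants_used, alpha=alpha),
        n_components,
    )
    return res
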