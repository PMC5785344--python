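"""Guide-gene co-expression screening by (optionally weighted) Pearson correlation.

Candidate genes are screened against a user-supplied list of guide genes
(e.g. known starch-biosynthesis genes) on a genes x samples expression
matrix; an edge is reported for every candidate x guide pair and flagged
when the correlation coefficient is >= the cutoff (default 0.6).  The
weighted variant normalises per-sample weights to sum to one and uses
weighted means and covariances; with equal weights it reduces exactly to
the ordinary Pearson coefficient.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EDGE_COLUMNS = ["candidate", "guide", "pcc", "passes_cutoff"]


def pearson(x: np.ndarray, y: np.ndarray,
            weights: np.ndarray | None = None) -> float:
    """Pearson correlation coefficient, optionally sample-weighted."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if weights is None:
        w = np.full(len(x), 1.0 / len(x))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative, same length, sum > 0")
        w = w / w.sum()
    dx = x - np.sum(w * x)
    dy = y - np.sum(w * y)
    vx = np.sum(w * dx * dx)
    vy = np.sum(w * dy * dy)
    if vx == 0 or vy == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(np.sum(w * dx * dy) / np.sqrt(vx * vy))


def screen_guides(matrix: pd.DataFrame, guide_genes: list[str],
                  candidates: list[str], cutoff: float = 0.6,
                  weights: np.ndarray | None = None) -> pd.DataFrame:
    """All candidate x guide correlations on a genes-by-samples matrix.

    Returns an edge table sorted by candidate then descending coefficient;
    ``passes_cutoff`` is ``pcc >= cutoff`` ("0.6 or greater").
    """
    missing = [g for g in list(guide_genes) + list(candidates)
               if g not in matrix.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    rows = []
    for cand in candidates:
        x = matrix.loc[cand].to_numpy(dtype=float)
        for guide in guide_genes:
            r = pearson(x, matrix.loc[guide].to_numpy(dtype=float), weights)
            rows.append((cand, guide, r, r >= cutoff))
    out = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return (out.sort_values(["candidate", "pcc"], ascending=[True, False])
            .reset_index(drop=True))


def make_coexpressed_matrix(guides: list[str],
                            planted: dict[str, tuple[str, float]],
                            n_samples: int = 40,
                            n_noise_genes: int = 0,
                            rng_seed: int | np.random.Generator = 0,
                            ) -> pd.DataFrame:
    """Synthetic expression matrix with planted guide correlations.

    Each guide profile is standard normal across samples; a planted gene
    ``g`` mapped to ``(guide, alpha)`` is ``alpha * guide + sqrt(1 - alpha^2)
    * noise``, so its expected Pearson correlation with that guide is
    ``alpha``.  ``n_noise_genes`` adds independent-noise genes named
    ``noise_i``.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    profiles = {g: rng.normal(size=n_samples) for g in guides}
    data = dict(profiles)
    for gene, (guide, alpha) in planted.items():
        if not (-1 <= alpha <= 1):
            raise ValueError("alpha must be in [-1, 1]")
        noise = rng.normal(size=n_samples)
        data[gene] = alpha * profiles[guide] + np.sqrt(1 - alpha ** 2) * noise
    for i in range(n_noise_genes):
        data[f"noise_{i + 1}"] = rng.normal(size=n_samples)
    df = pd.DataFrame(data).T
    df.columns = [f"sample_{j + 1}" for j in range(n_samples)]
    return df
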