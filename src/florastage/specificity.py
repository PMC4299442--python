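"""Per-gene expression Z-scores across stages and their distributions.

The Z-score standardizes a gene's log2 RPKM profile across the selected
stages: ``Z = (X - mu) / sigma`` with ``mu`` and ``sigma`` the gene's mean
and standard deviation over those stages.  A large Z in one stage marks
stage-restricted expression; the histogram of one stage's Z-scores over all
genes summarizes how much of the transcriptome is skewed toward it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, ValidationError


@dataclass
class ZScoreResult:
    """Standardized profiles plus the per-gene moments they came from.

    ``degenerate`` flags sigma = 0 genes (constant across the selected
    stages); their z rows are 0 by policy so matrices stay aligned.
    """

    z: pd.DataFrame
    mu: pd.Series
    sigma: pd.Series
    degenerate: pd.Series


def zscores(
    log_expr: ExpressionMatrix,
    samples: list[str] | None = None,
    ddof: int = 1,
) -> ZScoreResult:
    """Standardize each gene's log2 expression over the selected samples.

    ``ddof=1`` (sample standard deviation) by default; with only 3-4 stages
    the choice is material, so it is exposed (``ddof=0`` for the population
    convention).
    """
    if log_expr.scale != "log2":
        raise ValidationError("zscores expects a log2-scale matrix")
    samples = list(log_expr.samples) if samples is None else list(samples)
    if len(samples) < 2:
        raise ValidationError("need at least two samples for a z-profile")
    unknown = [s for s in samples if s not in log_expr.samples]
    if unknown:
        raise ValidationError(f"unknown samples: {unknown}")

    x = log_expr.values[samples]
    mu = x.mean(axis=1)
    sigma = x.std(axis=1, ddof=ddof)
    degenerate = sigma == 0
    safe_sigma = sigma.replace(0, np.nan)
    z = x.sub(mu, axis=0).div(safe_sigma, axis=0)
    z[degenerate] = 0.0
    return ZScoreResult(z=z, mu=mu, sigma=sigma, degenerate=degenerate)


def z_histogram(
    result: ZScoreResult, sample: str, bin_width: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of one stage's Z-scores over all non-degenerate genes.

    Returns ``(edges, counts)`` over uniform bins of ``bin_width`` covering
    the observed range; counts sum to the number of non-degenerate genes.
    """
    if bin_width <= 0:
        raise ValidationError("bin width must be positive")
    if sample not in result.z.columns:
        raise ValidationError(f"sample {sample!r} not in z profiles")
    vals = result.z.loc[~result.degenerate, sample].to_numpy()
    if len(vals) == 0:
        return np.array([]), np.array([], dtype=int)
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return edges, counts


def plot_z_histogram(result: ZScoreResult, samples: list[str], path: str,
                     bin_width: float = 0.25) -> None:
    """Optional PNG of Z-score distributions (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for sample in samples:
        edges, counts = z_histogram(result, sample, bin_width)
        centers = (edges[:-1] + edges[1:]) / 2
        ax.plot(centers, counts, label=sample)
    ax.set_xlabel("Z-score")
    ax.set_ylabel("gene count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
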