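"""Pangenome commonality distribution and its exponential decomposition.

The commonality of a gene family is the number of distinct genomes it occurs
in.  Across a pangenome the histogram of commonalities is well described by a
sum of exponential components in k (the genome count): a steeply decaying
"cloud" of rare families, a flatter "shell" of moderately conserved ones, and
a rising "core" component peaking at k = G (present in nearly all genomes).
Component sizes are the integrals Σ_k a·exp(b·k) over k = 1..G.

The decomposition is fit by minimizing the Poisson deviance between observed
counts and the mixture — counts are counts, and least squares on log counts
breaks on empty bins.  The deviance surface is multimodal, so the fit is
multistarted from quantile-anchored log-linear initializations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .phylo_io import PresenceMatrix

__all__ = [
    "CommonalityHistogram",
    "ExponentialMixtureFit",
    "commonality_histogram",
    "fit_exponential_mixture",
    "component_sizes",
    "mixture_curve",
]

B_BOUND = 2.0  # |b| cap: decay faster than e^2 per genome is unidentifiable at integer k


@dataclass
class CommonalityHistogram:
    """counts[k-1] = number of families present in exactly k of G genomes."""

    G: int
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.G,):
            raise ValueError("counts must have one bin per k = 1..G")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def k(self) -> np.ndarray:
        return np.arange(1, self.G + 1)

    @property
    def n_families(self) -> float:
        return float(self.counts.sum())


@dataclass
class ExponentialMixtureFit:
    """Fitted mixture Σ_i a_i·exp(b_i·k), components ordered by exponent.

    With three components the first (most negative b) is the "cloud", the
    middle the "shell", the last (largest b) the "core".
    """

    amplitudes: np.ndarray
    exponents: np.ndarray
    G: int
    deviance: float
    converged: bool

    @property
    def n_components(self) -> int:
        return len(self.amplitudes)

    @property
    def component_sizes(self) -> np.ndarray:
        k = np.arange(1, self.G + 1)
        return np.array(
            [a * np.exp(b * k).sum() for a, b in zip(self.amplitudes, self.exponents)]
        )


def commonality_histogram(matrix: PresenceMatrix) -> CommonalityHistogram:
    """Exact commonality counts of a presence matrix (k = 0 rows excluded)."""
    if matrix.n_families == 0:
        raise ValueError("empty matrix")
    k = matrix.values.sum(axis=1)
    G = matrix.n_genomes
    counts = np.bincount(k[k > 0], minlength=G + 1)[1:]
    return CommonalityHistogram(G=G, counts=counts)


def mixture_curve(amplitudes, exponents, k) -> np.ndarray:
    a = np.asarray(amplitudes, dtype=float)[:, None]
    b = np.asarray(exponents, dtype=float)[:, None]
    return (a * np.exp(b * np.asarray(k)[None, :])).sum(axis=0)


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-300, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * (mu - y + term).sum())


def _loglinear_anchor(k: np.ndarray, y: np.ndarray) -> tuple:
    """Log-linear LS fit on positive bins of a k-window → (a, b)."""
    mask = y > 0
    if mask.sum() < 2:
        return max(float(y.mean()), 1e-3), 0.0
    slope, intercept = np.polyfit(k[mask], np.log(y[mask]), 1)
    return float(np.exp(intercept)), float(np.clip(slope, -B_BOUND, B_BOUND))


def fit_exponential_mixture(
    hist: CommonalityHistogram,
    n_components: int = 3,
    n_starts: int = 20,
    seed: int = 0,
) -> ExponentialMixtureFit:
    """Fit an exponential mixture to a commonality histogram.

    Minimizes Poisson deviance over (log a_i, b_i) with |b_i| ≤ 2, multistart
    from log-linear fits anchored on equal thirds of the k range plus seeded
    jitter.  Components are returned ordered by increasing exponent.
    """
    y = hist.counts
    k = hist.k.astype(float)
    if (y > 0).sum() < 2 * n_components:
        raise ValueError(
            f"need >= {2 * n_components} nonzero bins for {n_components} components"
        )
    rng = np.random.default_rng(seed)

    windows = np.array_split(np.arange(hist.G), n_components)
    anchors = [_loglinear_anchor(k[w], y[w]) for w in windows]

    def objective(x):
        a = np.exp(x[:n_components])
        b = x[n_components:]
        return _poisson_deviance(y, mixture_curve(a, b, k))

    bounds = [(-30.0, 40.0)] * n_components + [(-B_BOUND, B_BOUND)] * n_components

    best = None
    for start in range(n_starts):
        x0 = np.empty(2 * n_components)
        for i, (a0, b0) in enumerate(anchors):
            jitter_a = 1.0 if start == 0 else float(np.exp(rng.normal(0, 0.5)))
            jitter_b = 0.0 if start == 0 else float(rng.normal(0, 0.2))
            x0[i] = np.log(max(a0 * jitter_a, 1e-6))
            x0[n_components + i] = np.clip(b0 + jitter_b, -B_BOUND, B_BOUND)
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res

    a = np.exp(best.x[:n_components])
    b = best.x[n_components:]
    order = np.argsort(b)
    return ExponentialMixtureFit(
        amplitudes=a[order],
        exponents=b[order],
        G=hist.G,
        deviance=float(best.fun),
        converged=bool(best.success),
    )


def component_sizes(fit: ExponentialMixtureFit, round_to: int = 2) -> dict:
    """Component integrals S_i = Σ_{k=1..G} a_i·exp(b_i·k).

    Returns exact sizes and the same rounded to ``round_to`` significant
    figures; with three components they are labeled cloud/shell/core by
    increasing exponent.
    """
    from .gainloss import round_sig

    sizes = fit.component_sizes
    if fit.n_components == 3:
        labels = ["cloud", "shell", "core"]
    else:
        labels = [f"component{i + 1}" for i in range(fit.n_components)]
    return {
        "labels": labels,
        "exact": sizes,
        "rounded": np.array([round_sig(s, round_to) for s in sizes]),
        "total": float(sizes.sum()),
    }
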