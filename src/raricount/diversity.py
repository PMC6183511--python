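"""Species-accumulation feedback, rarefaction, and the asymptote fit.

The collector's curve — cumulative distinct taxa seen against cumulative
specimens counted — is the observer's live feedback on sampling
completeness.  A hyperbolic saturation (de Caprariis-type) fit

    S(n) = S_max · n / (b + n)

estimates the diversity at infinite sample size (S_max) together with the
half-saturation count b.  Rarefaction gives the expected richness of a
random subsample of n specimens drawn without replacement, either in closed
form (hypergeometric expectation) or by Monte Carlo, and underlies the
estimate of how much observed richness rare-mode counting gained over a
single-phase count of the same total size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammaln

from .engine import CountEvent, CountSession
from .stats import combined_estimates

__all__ = [
    "AccumulationCurve",
    "HyperbolicFit",
    "RarefactionResult",
    "collector_curve",
    "expected_richness",
    "rarefy_mc",
    "fit_decaprariis",
    "improvement_percent",
    "write_diversity_history",
    "read_diversity_history",
    "plot_collector_curve",
]

HISTORY_HEADER = ("specimens", "distinct_taxa")


@dataclass(frozen=True)
class AccumulationCurve:
    """Cumulative (specimens counted, distinct taxa seen) pairs."""

    n: np.ndarray
    S: np.ndarray

    def __len__(self) -> int:
        return len(self.n)

    def __eq__(self, other):
        if not isinstance(other, AccumulationCurve):
            return NotImplemented
        return np.array_equal(self.n, other.n) and np.array_equal(self.S, other.S)


@dataclass(frozen=True)
class HyperbolicFit:
    """Least-squares fit of S(n) = S_max·n/(b+n).

    ``converged`` is False when the optimizer failed or the asymptote is
    unidentifiable (parameters driven far beyond the data, as happens for a
    curvature-free, e.g. strictly linear, accumulation curve).
    """

    S_max: float
    b: float
    residual: float
    converged: bool

    def predict(self, n) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        return self.S_max * n / (self.b + n)


@dataclass(frozen=True)
class RarefactionResult:
    """Expected richness of a subsample of n specimens.

    ``replicates`` = 0 marks the closed-form hypergeometric expectation;
    otherwise ``expected_S`` is a Monte-Carlo mean with standard deviation
    ``sd`` across replicates.
    """

    n: int
    expected_S: float
    replicates: int = 0
    sd: float | None = None
    seed: int | None = None


def _event_ids(events: Iterable) -> list:
    return [ev.taxon_id if isinstance(ev, CountEvent) else ev for ev in events]


def collector_curve(events: Iterable) -> AccumulationCurve:
    """Collector's curve: point k is (k, distinct taxa among first k events).

    Accepts either raw taxon ids or :class:`CountEvent` objects.
    """
    ids = _event_ids(events)
    seen: set = set()
    S = np.empty(len(ids), dtype=int)
    for i, tid in enumerate(ids):
        seen.add(tid)
        S[i] = len(seen)
    return AccumulationCurve(n=np.arange(1, len(ids) + 1), S=S)


def _counts_array(counts) -> np.ndarray:
    if isinstance(counts, Mapping):
        arr = np.asarray(list(counts.values()), dtype=float)
    else:
        arr = np.asarray(list(counts), dtype=float)
    arr = arr[arr > 0]
    if arr.size and not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    return arr.astype(np.int64)


def _lchoose(a, b):
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


def expected_richness(counts, n: int) -> RarefactionResult:
    """Closed-form rarefaction: E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)].

    Binomial coefficients are evaluated in log space so counts in the tens
    of thousands pose no overflow problem.
    """
    arr = _counts_array(counts)
    N = int(arr.sum())
    if not 0 <= n <= N:
        raise ValueError(f"subsample size n={n} outside [0, N={N}]")
    if n == 0:
        return RarefactionResult(n=0, expected_S=0.0)
    denom = _lchoose(N, n)
    terms = np.zeros(arr.size)
    fits = (N - arr) >= n  # taxa that *can* be entirely absent from the subsample
    terms[fits] = np.exp(_lchoose((N - arr)[fits], n) - denom)
    return RarefactionResult(n=int(n), expected_S=float(np.sum(1.0 - terms)))


def rarefy_mc(counts, n: int, replicates: int, seed: int | None = None) -> RarefactionResult:
    """Monte-Carlo rarefaction: mean distinct taxa over random subsamples."""
    arr = _counts_array(counts)
    N = int(arr.sum())
    if not 0 <= n <= N:
        raise ValueError(f"subsample size n={n} outside [0, N={N}]")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(arr.size), arr)
    richness = np.empty(replicates, dtype=int)
    for r in range(replicates):
        idx = rng.choice(N, size=n, replace=False)
        richness[r] = np.unique(pool[idx]).size
    sd = float(richness.std(ddof=1)) if replicates > 1 else 0.0
    return RarefactionResult(
        n=int(n),
        expected_S=float(richness.mean()),
        replicates=int(replicates),
        sd=sd,
        seed=seed,
    )


def fit_decaprariis(curve: AccumulationCurve) -> HyperbolicFit:
    """Bounded nonlinear least-squares fit of the hyperbolic saturation curve.

    Start values are analytic: S_max₀ = 2·max(S), b₀ = the n at which S first
    reaches half its maximum.  A fit whose S_max runs far above the observed
    richness (no curvature in the data) is flagged ``converged=False``.
    """
    n = np.asarray(curve.n, dtype=float)
    S = np.asarray(curve.S, dtype=float)
    if np.unique(n).size < 3:
        raise ValueError("need at least 3 distinct points to fit")
    S_obs = S.max()
    if np.all(S == 1):
        raise ValueError("degenerate curve: richness constant at 1")
    if np.all(S == S[0]):
        # Flat curve: the saturation limit is the observed value itself.
        return HyperbolicFit(S_max=float(S[0]), b=0.0, residual=0.0, converged=True)

    b0 = float(n[np.argmax(S >= S_obs / 2.0)])
    ub_S, ub_b = 1e3 * S_obs, 1e6 * float(n.max())

    def resid(theta):
        smax, b = theta
        return smax * n / (b + n) - S

    res = least_squares(
        resid,
        x0=[2.0 * S_obs, max(b0, 1e-6)],
        bounds=([1e-9, 0.0], [ub_S, ub_b]),
    )
    S_max, b = map(float, res.x)
    residual = float(np.sqrt(np.mean(res.fun**2)))
    identifiable = S_max <= 20.0 * S_obs and b <= 100.0 * float(n.max())
    return HyperbolicFit(
        S_max=S_max,
        b=b,
        residual=residual,
        converged=bool(res.success) and identifiable,
    )


def improvement_percent(
    session: CountSession, replicates: int = 1000, seed: int | None = None
) -> float:
    """Percent gain in observed richness attributable to rare-mode counting.

    The counterfactual single-phase count is obtained by rarefying the
    reconstructed assemblage (combined effort-scaled estimates, rounded to
    integers) down to the number of specimens actually recorded; the return
    value is 100·(S_obs − S_norare)/S_norare.  Sessions without a rare phase
    return 0 by definition.
    """
    if not session.exclusions or session.tracks_rare == 0:
        return 0.0
    estimates = combined_estimates(session)
    rounded = {
        e.taxon_id: int(round(e.estimated_count))
        for e in estimates
        if round(e.estimated_count) >= 1
    }
    n_actual = len(session.events)
    S_obs = len({ev.taxon_id for ev in session.events})
    N_est = sum(rounded.values())
    n = min(n_actual, N_est)
    S_norare = rarefy_mc(rounded, n, replicates=replicates, seed=seed).expected_S
    return 100.0 * (S_obs - S_norare) / S_norare


def write_diversity_history(curve: AccumulationCurve, path) -> None:
    """Two-column tab-text history: specimens counted, cumulative taxa."""
    lines = ["\t".join(HISTORY_HEADER)]
    lines += [f"{int(n)}\t{int(S)}" for n, S in zip(curve.n, curve.S)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_diversity_history(path) -> AccumulationCurve:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or tuple(lines[0].split("\t")) != HISTORY_HEADER:
        raise ValueError(f"{path}: not a diversity history file")
    pairs = [line.split("\t") for line in lines[1:] if line.strip()]
    n = np.array([int(a) for a, _ in pairs], dtype=int)
    S = np.array([int(b) for _, b in pairs], dtype=int)
    return AccumulationCurve(n=n, S=S)


def plot_collector_curve(
    curve: AccumulationCurve, path, fit: HyperbolicFit | None = None
) -> None:
    """Save the collector's curve (optionally with its fit and asymptote).

    Output format follows the file extension (png, pdf, jpg, tif, ...).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.step(curve.n, curve.S, where="post", color="black", lw=1.5, label="observed")
    if fit is not None and len(curve):
        grid = np.linspace(1, curve.n.max(), 200)
        ax.plot(grid, fit.predict(grid), color="0.6", lw=1.2, label="hyperbolic fit")
        ax.axhline(fit.S_max, color="0.6", ls="--", lw=1.0, label="asymptote")
    ax.set_xlabel("specimens counted")
    ax.set_ylabel("distinct taxa seen")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
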