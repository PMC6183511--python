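"""Statistical core of two-phase rare-category counting.

The observer first counts every specimen ("full" phase), then excludes the
common taxa — those whose full-phase share exceeds a threshold, by rule of
thumb about 5% — and keeps counting only the rarities ("rare" phase) while
tracking effort in slide tracks.  Counts from the two phases are combined
by extrapolating each excluded taxon's full-phase count at its observed
per-track rate over the rare-phase effort:

    n̂_i = n_i · (1 + T_rare / T_full)          (excluded taxon i)
    n̂_j = n_full_j + n_rare_j                  (retained taxon j)

Relative proportions follow by normalization.  The module also provides the
binomial error landscape behind the cut-off rule of thumb: the relative
standard error of a proportion p estimated from N specimens is

    epsilon = z · sqrt(p (1 − p) / N) / p,

which for p = 5% and N = 2,000 is just below 10% of the abundance value —
the classical guidance for when a common taxon is "safe" to stop counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import CountSession, TallyTable
from .errors import StateError

__all__ = [
    "ExclusionSuggestion",
    "AbundanceEstimate",
    "ProportionError",
    "suggest_exclusions",
    "combined_estimates",
    "relative_error",
    "error_landscape",
    "eliminated_fraction",
    "threshold_summary",
]


@dataclass(frozen=True)
class ExclusionSuggestion:
    """One row of the descending-abundance exclusion dialog."""

    taxon_id: str
    n_full: int
    share: float
    excluded: bool


@dataclass(frozen=True)
class AbundanceEstimate:
    """Combined (both phases) abundance estimate for one taxon.

    ``basis`` is ``"effort_scaled"`` for excluded taxa (their rare-phase
    total is inferred from full-phase frequency and rare-phase effort, and
    may be fractional) and ``"observed"`` otherwise.
    """

    taxon_id: str
    estimated_count: float
    proportion: float
    basis: str


@dataclass(frozen=True)
class ProportionError:
    """Relative error of an estimated proportion p from N counted specimens."""

    p: float
    N: int
    z: float
    epsilon: float

    @property
    def band(self) -> tuple[float, float]:
        """The implied abundance interval p·(1 ± epsilon)."""
        return (self.p * (1.0 - self.epsilon), self.p * (1.0 + self.epsilon))


def suggest_exclusions(
    tally: TallyTable, threshold: float
) -> list[ExclusionSuggestion]:
    """Rank counted taxa by full-phase abundance and flag those above threshold.

    Shares are computed on full-phase counts only (the dialog appears at the
    mode switch, before any rare counts exist).  Taxa are ordered by
    descending count, ties broken by taxon id; zero-count taxa are omitted.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    N = tally.N_full
    if N <= 0:
        raise ValueError("empty tally: no full-phase counts")
    rows = sorted(
        ((tid, n) for tid, n in tally.n_full.items() if n > 0),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return [
        ExclusionSuggestion(tid, n, n / N, n / N > threshold) for tid, n in rows
    ]


def combined_estimates(session: CountSession) -> list[AbundanceEstimate]:
    """Effort-scaled combination of full- and rare-phase counts.

    With no rare phase (no exclusions or zero rare-phase tracks) this is the
    identity: estimates equal raw totals.  Estimates are returned in
    descending order of estimated count (ties by taxon id) and their
    proportions sum to one.
    """
    tally = session.tally()
    T_full, T_rare = session.tracks_full, session.tracks_rare
    if session.exclusions and T_rare > 0 and T_full == 0:
        raise StateError(
            "effort undefined: rare phase present but no full-phase tracks recorded"
        )
    factor = 1.0 + (T_rare / T_full if (T_rare > 0 and T_full > 0) else 0.0)
    estimates: list[tuple[str, float, str]] = []
    for tid in tally.taxon_ids():
        if tid in session.exclusions:
            estimates.append((tid, tally.n_full[tid] * factor, "effort_scaled"))
        else:
            estimates.append((tid, float(tally.total(tid)), "observed"))
    total = sum(e[1] for e in estimates)
    if total <= 0:
        raise ValueError("no counts recorded: proportions undefined")
    estimates.sort(key=lambda e: (-e[1], e[0]))
    return [
        AbundanceEstimate(tid, count, count / total, basis)
        for tid, count, basis in estimates
    ]


def relative_error(p: float, N: int, z: float = 1.0) -> ProportionError:
    """Binomial relative error epsilon = z·sqrt(p(1−p)/N)/p.

    ``z`` is the standard-normal multiplier: 1 gives the relative standard
    error, 1.96 a 95% band.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if not np.isfinite(z) or z <= 0:
        raise ValueError(f"z must be positive and finite, got {z}")
    eps = z * np.sqrt(p * (1.0 - p) / N) / p
    return ProportionError(p=float(p), N=int(N), z=float(z), epsilon=float(eps))


def error_landscape(
    p_grid: Sequence[float], N_grid: Sequence[int], z: float = 1.0
) -> pd.DataFrame:
    """Elementwise relative error on a p × N grid.

    Returns a DataFrame indexed by p with one column per N.  Along any row
    epsilon scales as 1/sqrt(N); the whole landscape is linear in z.
    """
    p = np.asarray(list(p_grid), dtype=float)
    N = np.asarray(list(N_grid), dtype=float)
    if p.size == 0 or N.size == 0:
        raise ValueError("empty grid")
    if np.any((p <= 0) | (p >= 1)) or np.any(N < 1):
        raise ValueError("grid values out of range: need 0 < p < 1 and N >= 1")
    if not np.isfinite(z) or z <= 0:
        raise ValueError(f"z must be positive and finite, got {z}")
    eps = z * np.sqrt(p[:, None] * (1.0 - p[:, None]) / N[None, :]) / p[:, None]
    return pd.DataFrame(eps, index=pd.Index(p, name="p"), columns=pd.Index(N.astype(int), name="N"))


def eliminated_fraction(tally: TallyTable, exclusions: Iterable[str]) -> float:
    """Fraction of full-phase specimens belonging to the excluded taxa.

    This is the share of the population the observer no longer has to stop
    for during rare-phase counting.
    """
    N = tally.N_full
    if N <= 0:
        raise ValueError("empty tally: no full-phase counts")
    return sum(tally.n_full.get(tid, 0) for tid in set(exclusions)) / N


def threshold_summary(
    tables: Sequence[Mapping[str, float] | pd.Series],
    p_grid: Sequence[float],
) -> pd.DataFrame:
    """Dataset-level summaries of candidate exclusion thresholds.

    For every threshold p, over a collection of per-sample relative-abundance
    tables, computes:

    - ``frac_samples_any_above``: fraction of samples with at least one
      species above p (a threshold is only usable where this is 1 — every
      sample must have something to exclude);
    - ``frac_species_any_above``: fraction of all species that exceed p in at
      least one sample;
    - the distribution over samples of the cumulative specimen proportion in
      species above p (``cum_prop_mean``/``_q25``/``_q75``/``_min``/``_max``)
      — the effort saved by skipping them;
    - ``mean_species_frac_above``: mean over samples of the within-sample
      fraction of species above p.

    All three headline curves are monotone non-increasing in p.
    """
    if len(tables) == 0:
        raise ValueError("need at least one sample table")
    series = []
    for i, t in enumerate(tables):
        s = pd.Series(t, dtype=float)
        if s.empty or not np.isclose(s.sum(), 1.0, atol=1e-6):
            raise ValueError(f"sample {i}: proportions must sum to 1")
        if (s < 0).any():
            raise ValueError(f"sample {i}: negative proportion")
        series.append(s[s > 0])
    all_species = sorted(set().union(*[set(s.index) for s in series]))
    rows = []
    for p in p_grid:
        above = [s[s > p] for s in series]
        cum = np.array([a.sum() for a in above])
        rows.append(
            {
                "p": p,
                "frac_samples_any_above": float(np.mean([len(a) > 0 for a in above])),
                "frac_species_any_above": len(
                    set().union(*[set(a.index) for a in above])
                )
                / len(all_species),
                "cum_prop_mean": float(cum.mean()),
                "cum_prop_q25": float(np.quantile(cum, 0.25)),
                "cum_prop_q75": float(np.quantile(cum, 0.75)),
                "cum_prop_min": float(cum.min()),
                "cum_prop_max": float(cum.max()),
                "mean_species_frac_above": float(
                    np.mean([len(a) / len(s) for a, s in zip(above, series)])
                ),
            }
        )
    return pd.DataFrame(rows).set_index("p")
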