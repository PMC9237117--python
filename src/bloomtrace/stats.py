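"""Ensemble contrasts: group time series and the offshore-exposure quantile.

Two summaries drive the analysis. First, per-offset means and population
standard deviations of an environmental variable within the bloom and
non-bloom groups (discarded drifters excluded) — the time-aligned envelope
view of the two ensembles. Second, a single offshore-exposure statistic: for
each bloom drifter take its minimum distance to coast over the final
``window`` days before the event; the reported threshold D is the
(1 - coverage) nearest-rank quantile of those minima, i.e. the distance such
that a fraction ``coverage`` of bloom parcels never came closer than D to
the coast inside the window (default: 90% coverage over 3 weeks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import EnvHistory
from .tracker import Label

__all__ = ["GroupSummary", "group_statistics", "offshore_exposure"]


@dataclass
class GroupSummary:
    variable: str
    times_rel_days: np.ndarray
    mean_bloom: np.ndarray
    sd_bloom: np.ndarray
    mean_nonbloom: np.ndarray
    sd_nonbloom: np.ndarray
    n_bloom: np.ndarray
    n_nonbloom: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (offset, group)."""
        rows = []
        for grp, m, s, n in (
            ("bloom", self.mean_bloom, self.sd_bloom, self.n_bloom),
            ("no_bloom", self.mean_nonbloom, self.sd_nonbloom, self.n_nonbloom),
        ):
            rows.append(
                pd.DataFrame(
                    {
                        "variable": self.variable,
                        "time_rel_days": self.times_rel_days,
                        "group": grp,
                        "mean": m,
                        "sd": s,
                        "n": n,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _masked_moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise mean, population sd and count over finite entries."""
    finite = np.isfinite(x)
    n = finite.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nansum(np.where(finite, x, 0.0), axis=0)
                        / np.maximum(n, 1), np.nan)
        dev2 = np.where(finite, (x - mean) ** 2, 0.0)
        sd = np.where(n > 0, np.sqrt(dev2.sum(axis=0) / np.maximum(n, 1)), np.nan)
    return mean, sd, n


def group_statistics(env: EnvHistory, variable: str) -> GroupSummary:
    """Per-offset mean and population sd for bloom vs. non-bloom drifters.

    Only active, non-missing samples contribute; discarded drifters are
    excluded entirely. Permutation of drifter order leaves the result
    unchanged.
    """
    if env.labels is None:
        raise ValueError("environment history carries no bloom labels")
    x = env.variable(variable)
    bloom = env.labels == Label.BLOOM
    nonbloom = env.labels == Label.NO_BLOOM
    if not bloom.any() or not nonbloom.any():
        raise ValueError("need at least one bloom and one no_bloom drifter")
    mb, sb, nb = _masked_moments(x[bloom])
    mn, sn, nn = _masked_moments(x[nonbloom])
    return GroupSummary(
        variable=variable,
        times_rel_days=env.times_rel / 86400.0,
        mean_bloom=mb,
        sd_bloom=sb,
        mean_nonbloom=mn,
        sd_nonbloom=sn,
        n_bloom=nb,
        n_nonbloom=nn,
    )


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank quantile: the ceil(q*n)-th smallest value (rank >= 1)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("empty sample")
    rank = max(1, int(np.ceil(q * n)))
    return float(v[rank - 1])


def offshore_exposure(
    env: EnvHistory, window_days: float = 21.0, coverage: float = 0.90
) -> float:
    """Distance D (nm) that ``coverage`` of bloom parcels never undercut.

    Per bloom drifter: minimum distance to coast over offsets within
    ``window_days`` of the event; D is the (1 - coverage) nearest-rank
    quantile of those per-drifter minima. Monotone non-increasing in
    ``coverage`` by construction of the rank.
    """
    if env.labels is None or not (env.labels == Label.BLOOM).any():
        raise ValueError("no bloom-labelled drifters")
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must be in (0, 1]")
    in_window = np.abs(env.times_rel) <= window_days * 86400.0 + 1e-6
    if not in_window.any():
        raise ValueError("window contains no trajectory offsets")
    d = env.dist_coast_nm[env.labels == Label.BLOOM][:, in_window]
    with np.errstate(all="ignore"):
        minima = np.nanmin(d, axis=1)
    minima = minima[np.isfinite(minima)]
    if minima.size == 0:
        raise ValueError("no bloom drifter has a valid distance sample in window")
    return nearest_rank_quantile(minima, 1.0 - coverage)
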