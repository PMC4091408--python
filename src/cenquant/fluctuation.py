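"""Stochastic-fluctuation counting of segregating units on sister centromeres.

During replication, pre-assembled CENP-A nucleosomes redistribute randomly
onto the two sister chromatids. If a centromere carries ``N`` independently
segregating units of equal fluorescence ``alpha``, the sister intensity
difference ``delta = |I1 - I2|`` satisfies ``E[delta^2] = alpha * Sigma``
where ``Sigma = I1 + I2`` (binomial partitioning with p = 1/2). The
fluorescence per segregating unit is therefore estimated as the mean of
``delta^2 / Sigma`` over all sister pairs of one experiment and cell line,
and each centromere's unit number as ``Sigma / alpha``.

Each unit holds at least one nucleosome with two CENP-A molecules, so
``2 x units`` is a *minimum* molecule count; dividing by the cell line's
expression level relative to wild type converts it to the wild-type scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SisterPair",
    "UnitEstimate",
    "RandomPairRound",
    "pair_from_intensities",
    "pairs_from_table",
    "estimate_alpha",
    "units_per_centromere",
    "molecules_from_units",
    "random_pair_control",
    "analyze_experiment",
]


@dataclass
class SisterPair:
    i1: float
    i2: float
    cell_id: object = None
    experiment_id: object = None

    @property
    def delta(self) -> float:
        return abs(self.i1 - self.i2)

    @property
    def sigma(self) -> float:
        return self.i1 + self.i2


@dataclass
class UnitEstimate:
    """Segregating units per centromere for one experiment scope."""

    alpha: float
    units: np.ndarray            # per-pair Sigma / alpha
    units_mean: float
    n_pairs: int
    scope: str = ""
    n_rejected: int = 0          # pairs dropped (both intensities <= 0)
    n_sigma_zero: int = 0        # pairs excluded from alpha (Sigma = 0)


@dataclass
class RandomPairRound:
    alpha: float
    units_mean: float
    p_value: float               # Welch t test vs the sister-pair units


def pair_from_intensities(i1: float, i2: float, cell_id=None,
                          experiment_id=None):
    """Build a sister pair; returns ``(pair, reason)``.

    A pair with both intensities <= 0 is rejected (``pair`` is None and
    ``reason`` is ``"nonpositive"``); otherwise ``reason`` is None.
    """
    if i1 <= 0 and i2 <= 0:
        return None, "nonpositive"
    return SisterPair(float(i1), float(i2), cell_id, experiment_id), None


def pairs_from_table(table: pd.DataFrame) -> tuple[list, dict]:
    """Convert an ``(experiment_id, cell_id, pair_id, i1, i2)`` table to pairs.

    Returns the accepted pairs and a counter dict of rejection reasons.
    """
    pairs, log = [], {"nonpositive": 0}
    for row in table.itertuples(index=False):
        pair, reason = pair_from_intensities(
            row.i1, row.i2,
            getattr(row, "cell_id", None), getattr(row, "experiment_id", None),
        )
        if pair is None:
            log[reason] += 1
        else:
            pairs.append(pair)
    return pairs, log


def estimate_alpha(pairs) -> float:
    """Fluorescence per segregating unit: mean of delta^2/Sigma over pairs.

    Pairs with ``Sigma = 0`` are excluded (the ratio is undefined). Raises if
    fewer than two usable pairs remain or if every delta is zero (no
    fluctuation signal).
    """
    vals = [p.delta ** 2 / p.sigma for p in pairs if p.sigma > 0]
    if len(vals) < 2:
        raise ValueError("at least 2 pairs with Sigma > 0 are required")
    alpha = float(np.mean(vals))
    if alpha == 0:
        raise ValueError("no fluctuation signal; alpha undefined")
    return alpha


def units_per_centromere(pairs, alpha: float, scope: str = "") -> UnitEstimate:
    """Per-pair unit numbers ``Sigma / alpha`` and their mean."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    sigmas = np.array([p.sigma for p in pairs], dtype=float)
    n_sigma_zero = int((sigmas <= 0).sum())
    units = sigmas[sigmas > 0] / alpha
    return UnitEstimate(
        alpha=alpha,
        units=units,
        units_mean=float(units.mean()) if units.size else np.nan,
        n_pairs=int(units.size),
        scope=scope,
        n_sigma_zero=n_sigma_zero,
    )


def molecules_from_units(units: float, copies_per_nucleosome: int = 2,
                         relative_level: float = 1.0) -> float:
    """Minimum molecule count on the wild-type scale.

    Each segregating unit carries >= 1 nucleosome with
    ``copies_per_nucleosome`` CENP-A molecules; dividing by the measuring cell
    line's expression level relative to wild type rescales the estimate.
    The result is a lower bound because units may group several nucleosomes.
    """
    if relative_level <= 0:
        raise ValueError("relative_level must be > 0")
    return units * copies_per_nucleosome / relative_level


def random_pair_control(table: pd.DataFrame, n_rounds: int = 3,
                        seed: int = 0) -> list[RandomPairRound]:
    """Random re-pairing control within each experiment.

    All measured sister intensities of an experiment are pooled and re-paired
    at random (``n_rounds`` independent rounds); each round's alpha and units
    are recomputed and compared to the sister-pair result with a two-sided
    Welch t test on the per-pair unit numbers. Sister pairing carries a real
    statistical correlation (sisters share one parental total), so the control
    should differ significantly whenever the partitioning signal is real.
    """
    rng = np.random.default_rng(seed)
    pairs, _ = pairs_from_table(table)
    sister = units_per_centromere(pairs, estimate_alpha(pairs), scope="sister")
    pool = np.concatenate([[p.i1 for p in pairs], [p.i2 for p in pairs]])
    rounds = []
    for _ in range(n_rounds):
        perm = rng.permutation(pool)
        rand_pairs = [SisterPair(a, b) for a, b in zip(perm[0::2], perm[1::2])]
        est = units_per_centromere(rand_pairs, estimate_alpha(rand_pairs),
                                   scope="random")
        t = stats.ttest_ind(est.units, sister.units, equal_var=False)
        rounds.append(RandomPairRound(alpha=est.alpha,
                                      units_mean=est.units_mean,
                                      p_value=float(t.pvalue)))
    return rounds


def analyze_experiment(table: pd.DataFrame,
                       scope_cols=("experiment_id",)) -> dict:
    """Alpha and unit estimates per experiment scope (experiment-and-cell-line).

    Pooling across experiments is deliberately opt-in: call with a pre-merged
    table and a constant scope column to pool.
    """
    results = {}
    for key, sub in table.groupby(list(scope_cols)):
        pairs, log = pairs_from_table(sub)
        alpha = estimate_alpha(pairs)
        est = units_per_centromere(pairs, alpha, scope=str(key))
        est.n_rejected = log["nonpositive"]
        results[key if len(scope_cols) > 1 else key[0] if isinstance(key, tuple) else key] = est
    return results
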