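"""Deviation-score differential expression with a permutation null.

For each gene, the sensitive (CR) group defines a per-gene *normal range*
``[mean - sd, mean + sd]`` (sample sd).  Each resistant (NOCR) sample
contributes its clamped excursion beyond that range,

    contribution_i = X_i - x_max  if X_i > x_max
                     X_i - x_min  if X_i < x_min
                     0            otherwise,

and the gene's raw score is the signed sum of contributions over the
resistant group (up- and down-excursions can cancel); the absolute score
sums |contribution| instead.  Significance comes from re-drawing the
sensitive/resistant labels at random (preserving group sizes), recomputing
the score under each relabelling, and comparing magnitudes; the empirical
p-value uses the add-one correction ``(count + 1) / (B + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "NormalRange",
    "PermutationConfig",
    "normal_range",
    "deviation_score",
    "permutation_pvalue",
    "detect_degs",
]


@dataclass(frozen=True)
class NormalRange:
    x_min: float
    x_max: float
    n_sensitive: int


@dataclass
class PermutationConfig:
    """Settings for the permutation test.

    ``statistic="signed"`` tests the signed score two-sided (|score|);
    ``"absolute"`` tests the nonnegative absolute-deviation score upper-tail.
    """

    n_permutations: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    statistic: str = "signed"

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise InputError("n_permutations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise InputError("alpha must lie in (0, 1)")
        if self.statistic not in ("signed", "absolute"):
            raise InputError(f"unknown statistic {self.statistic!r}")


def normal_range(sensitive_values) -> NormalRange:
    """Normal range mean +/- sd (sample sd) of the sensitive group."""
    v = np.asarray(sensitive_values, dtype=float)
    if v.size < 2:
        raise InputError("normal range requires >= 2 sensitive values")
    mu = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        warnings.warn("zero-variance sensitive group: degenerate normal range", RuntimeWarning)
    return NormalRange(mu - sd, mu + sd, int(v.size))


def deviation_score(resistant_values, rng: NormalRange) -> tuple[float, float]:
    """Signed and absolute cumulative deviation beyond the normal range."""
    v = np.asarray(resistant_values, dtype=float)
    if v.size == 0:
        raise InputError("deviation score requires >= 1 resistant value")
    over = np.maximum(v - rng.x_max, 0.0)
    under = np.minimum(v - rng.x_min, 0.0)
    contrib = over + under
    return float(contrib.sum()), float(np.abs(contrib).sum())


def _scores_matrix(X: np.ndarray, sens: np.ndarray, res: np.ndarray):
    """Vectorized signed/absolute scores for every gene row of ``X``."""
    S = X[:, sens]
    mu = S.mean(axis=1)
    sd = S.std(axis=1, ddof=1)
    hi = mu + sd
    lo = mu - sd
    R = X[:, res]
    contrib = np.maximum(R - hi[:, None], 0.0) + np.minimum(R - lo[:, None], 0.0)
    return contrib.sum(axis=1), np.abs(contrib).sum(axis=1), contrib


def permutation_pvalue(all_values, n1: int, n2: int, observed: float,
                       cfg: PermutationConfig) -> float:
    """Empirical p-value for one gene's observed score.

    ``all_values`` concatenates the n1 sensitive and n2 resistant values in
    any order; each of B seeded permutations assigns the first n1 shuffled
    values to the sensitive role.  ``observed`` is the signed raw score for
    the signed statistic (compared as |score|) or the absolute score for
    the absolute statistic.
    """
    cfg.validate()
    v = np.asarray(all_values, dtype=float)
    if v.size != n1 + n2:
        raise InputError(f"expected {n1 + n2} values, got {v.size}")
    if n1 < 2:
        raise InputError("n1 must be >= 2 (normal range undefined otherwise)")
    X = v[None, :]
    rng = np.random.default_rng(cfg.seed)
    obs = abs(observed) if cfg.statistic == "signed" else float(observed)
    count = 0
    n = n1 + n2
    for _ in range(cfg.n_permutations):
        perm = rng.permutation(n)
        raw, absv, _ = _scores_matrix(X, perm[:n1], perm[n1:])
        stat = abs(raw[0]) if cfg.statistic == "signed" else absv[0]
        if stat >= obs:
            count += 1
    return (count + 1) / (cfg.n_permutations + 1)


def detect_degs(m: pd.DataFrame, ann: pd.DataFrame, cfg: PermutationConfig) -> pd.DataFrame:
    """Score and permutation-test every gene of ``m`` against the CR normal range.

    Returns a DataFrame indexed by gene with columns ``raw_score``,
    ``abs_score``, ``p_value``, ``q_value`` (Benjamini-Hochberg, reported
    but not used for calls), ``significant`` (p < alpha) and ``direction``
    (up/down/mixed/none).  One shared, seeded sequence of label shuffles is
    reused across genes.
    """
    from .pathway_analysis import bh_fdr

    cfg.validate()
    missing = [s for s in m.columns if s not in ann.index or ann.loc[s, "response"] == ""]
    if missing:
        raise InputError(f"samples without response annotation: {missing[:5]}")
    resp = ann.loc[m.columns, "response"]
    sens = np.flatnonzero((resp == "CR").to_numpy())
    res = np.flatnonzero((resp == "NOCR").to_numpy())
    if sens.size < 2:
        raise InputError("need >= 2 CR samples")
    if res.size < 1:
        raise InputError("need >= 1 NOCR sample")

    X = m.to_numpy(dtype=float)
    raw, absv, contrib = _scores_matrix(X, sens, res)
    obs = np.abs(raw) if cfg.statistic == "signed" else absv

    pool = np.concatenate([sens, res])
    n1 = sens.size
    rng = np.random.default_rng(cfg.seed)
    count = np.zeros(X.shape[0], dtype=np.int64)
    for _ in range(cfg.n_permutations):
        perm = rng.permutation(pool)
        r_b, a_b, _ = _scores_matrix(X, perm[:n1], perm[n1:])
        stat = np.abs(r_b) if cfg.statistic == "signed" else a_b
        count += stat >= obs
    p = (count + 1) / (cfg.n_permutations + 1)

    pos = (contrib > 0).any(axis=1)
    neg = (contrib < 0).any(axis=1)
    direction = np.where(
        absv == 0, "none", np.where(pos & ~neg, "up", np.where(neg & ~pos, "down", "mixed"))
    )
    return pd.DataFrame(
        {
            "raw_score": raw,
            "abs_score": absv,
            "p_value": p,
            "q_value": bh_fdr(p),
            "significant": p < cfg.alpha,
            "direction": direction,
        },
        index=m.index,
    )
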