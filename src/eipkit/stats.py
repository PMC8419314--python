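"""Group statistics: EIP-change test and power analysis.

The EIP-change test asks whether per-pulse IC50s differ systematically across
the pulses of one protocol section, treating measurements (cell ensembles) as
blocks.  The default is the Friedman rank test on log IC50; for small numbers
of blocks a within-block permutation version of the same statistic is
available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps
from statsmodels.stats.power import TTestIndPower

__all__ = ["EIPChangeTest", "eip_change_test", "power_detectable_effect"]


@dataclass(frozen=True)
class EIPChangeTest:
    statistic: float
    p_value: float
    method: str
    n_blocks: int
    n_conditions: int


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Friedman chi-square from within-block ranks (blocks x conditions)."""
    n, k = ranks.shape
    rj = ranks.sum(axis=0)
    return float(12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1))


def eip_change_test(
    ic50s: np.ndarray,
    method: str = "friedman",
    n_permutations: int = 5000,
    seed: Optional[int] = None,
) -> EIPChangeTest:
    """Test for systematic EIP change across pulses within a section.

    Parameters
    ----------
    ic50s : array (n_measurements, n_pulses)
        Per-measurement IC50s for the pulses of one section.  The test runs
        on log IC50 (ranks are log-invariant; logging documents intent).
    method : "friedman" (asymptotic) or "permutation" (within-block label
        permutation of the same rank statistic).  The asymptotic p-value uses
        the Iman-Davenport F refinement of the Friedman chi-square, which is
        markedly more accurate for the small block counts (n ~ 6) this
        analysis deals in; the reported statistic is the Friedman chi-square.
    """
    x = np.log(np.asarray(ic50s, dtype=float))
    if x.ndim != 2:
        raise ValueError("ic50s must be 2-D (measurements x pulses)")
    n, k = x.shape
    if n < 2:
        raise ValueError("at least 2 measurements (blocks) are required")
    if k < 3:
        raise ValueError("at least 3 pulses (conditions) are required")

    if method == "friedman":
        ranks = sps.rankdata(x, axis=1)
        chi = _friedman_statistic(ranks)
        denom = n * (k - 1) - chi
        if denom <= 0:
            p = float(sps.chi2.sf(chi, k - 1))
        else:
            F = (n - 1) * chi / denom
            p = float(sps.f.sf(F, k - 1, (n - 1) * (k - 1)))
        return EIPChangeTest(float(chi), min(p, 1.0), method, n, k)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        ranks = sps.rankdata(x, axis=1)
        obs = _friedman_statistic(ranks)
        count = 0
        for _ in range(n_permutations):
            perm = np.array([rng.permutation(row) for row in ranks])
            if _friedman_statistic(perm) >= obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_permutations)
        return EIPChangeTest(obs, float(p), method, n, k)
    raise ValueError(f"unknown method {method!r}")


def power_detectable_effect(n: int, effect_sd: float, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t-test (noncentral-t, n per group).

    ``effect_sd`` is the standardized effect size (difference in units of the
    common standard deviation).  With n = 6 per group, an effect of 2 SD is
    detectable with power >= 0.8 at alpha = 0.05.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if effect_sd < 0:
        raise ValueError("effect_sd must be >= 0")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if effect_sd == 0:
        return float(alpha)
    return float(
        TTestIndPower().power(
            effect_size=effect_sd, nobs1=n, alpha=alpha, ratio=1.0,
            alternative="two-sided",
        )
    )
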