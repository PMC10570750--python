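"""Gene-set overlap statistics and IL1b / calcipotriol rescue patterns.

The overlap test is the upper-tail hypergeometric probability
P(X >= k) for X ~ Hypergeom(N, K, n): drawing a query set of size n from a
universe of N genes of which K belong to the reference set, and observing k
in the intersection.  The tail is evaluated in log space so that p-values
far below float underflow (< 1e-300) remain meaningful.  The universe size
N must always be supplied explicitly: it determines the p-value and has no
defensible default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "OverlapTest",
    "RescuePattern",
    "hypergeometric_overlap",
    "overlap_fraction",
    "classify_rescue",
    "rescue_set_test",
]


@dataclass
class OverlapTest:
    k: int
    n: int
    K: int
    N: int
    p_upper: float
    log10_p: float
    fold: float


@dataclass
class RescuePattern:
    gene_id: str
    level_ctrl: float
    level_il1b: float
    level_il1b_cal: float
    pattern: str  # suppressed_rescued / suppressed_not_rescued / not_suppressed
    flag: str | None = None


def hypergeometric_overlap(k: int, n: int, K: int, N: int) -> OverlapTest:
    """Upper-tail hypergeometric overlap test with log-space stability."""
    if not 0 <= k:
        raise ValueError(f"bound violated: 0 <= k (k={k})")
    if k > min(n, K):
        raise ValueError(f"bound violated: k <= min(n, K) (k={k}, n={n}, K={K})")
    if max(n, K) > N:
        raise ValueError(f"bound violated: max(n, K) <= N (n={n}, K={K}, N={N})")
    logp = stats.hypergeom.logsf(k - 1, N, K, n)
    p = float(np.exp(logp))
    fold = (k / n) / (K / N) if n > 0 and K > 0 else math.nan
    return OverlapTest(k, n, K, N, p, float(logp) / math.log(10), fold)


def overlap_fraction(k: int, n: int) -> int:
    """Percent overlap rounded half away from zero, as printed in prose."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return int(math.floor(100.0 * k / n + 0.5))


def classify_rescue(
    gene_id: str,
    ctrl: float,
    il1b: float,
    il1b_cal: float,
    suppress_frac: float = 0.30,
    rescue_tol: float = 0.15,
) -> RescuePattern:
    """Three-condition rescue call.

    A gene is suppressed when IL1b expression drops to at most
    (1 - suppress_frac) of control, and rescued when co-treatment brings it
    back within rescue_tol of the control level.
    """
    if min(ctrl, il1b, il1b_cal) < 0:
        raise ValueError("expression levels must be >= 0")
    if ctrl == 0:
        return RescuePattern(gene_id, ctrl, il1b, il1b_cal, "not_suppressed",
                             flag="undefined_ratio_ctrl_zero")
    suppressed = il1b <= (1.0 - suppress_frac) * ctrl
    if not suppressed:
        return RescuePattern(gene_id, ctrl, il1b, il1b_cal, "not_suppressed")
    rescued = abs(il1b_cal - ctrl) <= rescue_tol * ctrl
    pattern = "suppressed_rescued" if rescued else "suppressed_not_rescued"
    return RescuePattern(gene_id, ctrl, il1b, il1b_cal, pattern)


def rescue_set_test(
    regulated_genes: set[str],
    suppressed_set: set[str],
    rescued_set: set[str],
    universe_N: int,
) -> tuple[OverlapTest, OverlapTest]:
    """Overlap of a regulated-gene query against the IL1b-suppressed and
    calcipotriol-upregulated reference sets, against a shared universe."""
    if not regulated_genes:
        raise ValueError("empty query set")
    for name, s in (("query", regulated_genes), ("suppressed", suppressed_set),
                    ("rescued", rescued_set)):
        if len(s) > universe_N:
            raise ValueError(f"universe N={universe_N} smaller than {name} set")
    n = len(regulated_genes)
    t_sup = hypergeometric_overlap(
        len(regulated_genes & suppressed_set), n, len(suppressed_set), universe_N
    )
    t_res = hypergeometric_overlap(
        len(regulated_genes & rescued_set), n, len(rescued_set), universe_N
    )
    return t_sup, t_res
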