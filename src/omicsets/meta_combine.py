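"""Meta-analytic combination of per-platform set-level P-values.

When each platform is analyzed separately, every set carries D P-values
p_s^1..p_s^D. Two consensus summaries are provided:

* ``avgp`` — geometric mean, exp(mean(log p)); appropriate when evidence
  from several platforms is required.
* ``minp`` — minimum; appropriate when strong evidence from any single
  platform suffices. Reported uncorrected (its use here is ranking); a
  Bonferroni-style variant (D * min p, capped at 1) is available behind a
  flag for users who want calibrated significance.

Both combinations always lie within [min_d p_s^d, max_d p_s^d] and are
invariant to the platform order.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = ["avgp", "minp", "combine_tables"]

logger = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny


def _clean(pvalues: Iterable[float]) -> np.ndarray:
    p = np.asarray([v for v in pvalues if not np.isnan(v)], dtype=float)
    if p.size == 0:
        raise InputError("no available platform p-values to combine")
    if (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    if (p == 0).any():
        logger.warning("p-value of exactly 0 clamped to %.3g before combining", _TINY)
        p = np.maximum(p, _TINY)
    return p


def avgp(pvalues: Iterable[float]) -> float:
    """Geometric mean of the available platform p-values (log-domain)."""
    p = _clean(pvalues)
    return float(np.exp(np.mean(np.log(p))))


def minp(pvalues: Iterable[float], bonferroni: bool = False) -> float:
    """Minimum of the available platform p-values.

    With ``bonferroni=True`` returns min(1, D * min p) instead; the ranking
    of sets is unchanged, only the scale is calibrated.
    """
    p = _clean(pvalues)
    m = float(p.min())
    return min(1.0, len(p) * m) if bonferroni else m


def combine_tables(
    platform_tables: Sequence[pd.DataFrame],
    method: str = "AvgP",
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Combine per-platform SetResultTables into one consensus table.

    ``platform_tables`` are outputs of the stage-II tests (one per platform,
    columns ``set_id, method, n_genes, statistic, p``). Sets missing from a
    platform's table are combined over the platforms that tested them.
    """
    if method not in ("AvgP", "MinP"):
        raise InputError(f"method must be 'AvgP' or 'MinP', got {method!r}")
    if len(platform_tables) < 2:
        raise InputError("need p-values from at least two platforms")
    wide = pd.concat(
        [t.set_index("set_id")["p"].rename(i) for i, t in enumerate(platform_tables)],
        axis=1,
    )
    fn = avgp if method == "AvgP" else (lambda v: minp(v, bonferroni))
    combined = wide.apply(lambda row: fn(row.to_numpy()), axis=1)
    n_genes = (
        pd.concat([t.set_index("set_id")["n_genes"] for t in platform_tables], axis=1)
        .max(axis=1)
        .astype(int)
    )
    out = pd.DataFrame(
        {
            "set_id": combined.index,
            "method": method,
            "n_genes": n_genes.loc[combined.index].to_numpy(),
            "statistic": combined.to_numpy(),
            "p": combined.to_numpy(),
        }
    ).reset_index(drop=True)
    return out
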