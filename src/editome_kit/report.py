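"""Summary arithmetic: share percentages, tissue-occurrence tallies and
the assembled end-of-run report."""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

log = logging.getLogger(__name__)


def percent_share(numerator: float, denominator: float, decimals: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up at ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be within [0, denominator]")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    q = Decimal(10) ** -decimals
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def tissue_occurrence_summary(tissue_sets: dict) -> dict:
    """Counts and shares of entities seen in exactly one vs >= 2 tissues.

    ``tissue_sets`` maps entity -> set of tissues it occurs in.
    """
    single = sum(1 for s in tissue_sets.values() if len(s) == 1)
    multi = sum(1 for s in tissue_sets.values() if len(s) >= 2)
    total = single + multi
    return {
        "n_total": total,
        "n_single_tissue": single,
        "n_multi_tissue": multi,
        "pct_single_tissue": percent_share(single, total) if total else 0.0,
        "pct_multi_tissue": percent_share(multi, total) if total else 0.0,
    }


def build_report(stages: dict) -> pd.DataFrame:
    """Flatten per-stage summary dictionaries into one deterministic table.

    ``stages`` maps stage name -> dict of named counts/values; missing
    stages (value None) are reported as absent with a warning.
    """
    rows = []
    for stage in sorted(stages):
        values = stages[stage]
        if values is None:
            log.warning("stage %s missing from report inputs", stage)
            rows.append({"stage": stage, "metric": "absent", "value": None})
            continue
        for metric in sorted(values):
            rows.append({"stage": stage, "metric": metric, "value": values[metric]})
    return pd.DataFrame(rows, columns=["stage", "metric", "value"])
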