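"""Summary tables and derived statistics over per-variant labels.

``summarize`` tallies labels into the headline layout: one row per variant
class plus an ALL row, with columns recessive / dominant / no / hold /
total.  Both "not" hedges (definitely and possibly not destabilizing) fall
into the "no" column; recessive and dominant together are the
"structurally destabilizing" calls.

All percentages are rounded half-up — one decimal for shares of a class
total, nearest integer for the coarse ratios — matching the conventional
presentation of such tables.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

from .classifier import AnnotationLabel, HoldReason, Label
from .variant_effects import VariantClass

__all__ = ["SummaryTable", "summarize", "derived_stats", "round_half_up"]

CLASS_ORDER = [VariantClass.NONSENSE_SNP, VariantClass.FRAMESHIFT_INDEL,
               VariantClass.INFRAME_INDEL]
COLUMNS = ["recessive", "dominant", "no", "hold"]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero upward)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class SummaryTable:
    """Counts per variant class and label column, plus an ALL row."""

    def __init__(self, counts: pd.DataFrame):
        counts = counts.loc[[c.value for c in CLASS_ORDER], COLUMNS].astype(int)
        counts["total"] = counts.sum(axis=1)
        all_row = counts.sum(axis=0)
        self.counts = pd.concat([counts, all_row.to_frame("ALL").T])
        self.counts.index.name = "variant_class"

    @classmethod
    def from_rows(cls, rows: Mapping[VariantClass | str, tuple[int, int, int, int]],
                  ) -> "SummaryTable":
        """Build from per-class (recessive, dominant, no, hold) count rows."""
        data = {}
        for k, v in rows.items():
            key = k.value if isinstance(k, VariantClass) else str(k)
            data[key] = dict(zip(COLUMNS, v))
        return cls(pd.DataFrame.from_dict(data, orient="index"))

    def row(self, variant_class: VariantClass | str) -> pd.Series:
        key = (variant_class.value if isinstance(variant_class, VariantClass)
               else variant_class)
        return self.counts.loc[key]

    @property
    def all(self) -> pd.Series:
        return self.counts.loc["ALL"]

    def destabilizing(self, variant_class: VariantClass | str = "ALL") -> int:
        r = self.row(variant_class)
        return int(r["recessive"] + r["dominant"])

    def class_pct(self, variant_class: VariantClass | str, column: str,
                  decimals: int = 1) -> float:
        """Percentage of a class total falling into ``column`` (or
        ``"destabilizing"`` for recessive + dominant)."""
        r = self.row(variant_class)
        num = self.destabilizing(variant_class) if column == "destabilizing" \
            else int(r[column])
        return round_half_up(100.0 * num / int(r["total"]), decimals)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


def summarize(labels: Iterable[tuple[VariantClass, AnnotationLabel]],
              ) -> SummaryTable:
    """Tally (variant class, annotation) pairs into a :class:`SummaryTable`."""
    counts = pd.DataFrame(0, index=[c.value for c in CLASS_ORDER],
                          columns=COLUMNS)
    for vclass, ann in labels:
        counts.loc[vclass.value, ann.summary_column] += 1
    return SummaryTable(counts)


def derived_stats(s: SummaryTable,
                  hold_reasons: Iterable[HoldReason] | None = None) -> dict:
    """Headline ratios derived from the summary table.

    When per-variant ``hold_reasons`` are supplied, the hold column is also
    split into no-structure vs. other causes.
    """
    ns, fs, inf = (VariantClass.NONSENSE_SNP, VariantClass.FRAMESHIFT_INDEL,
                   VariantClass.INFRAME_INDEL)

    def pct(num: int, den: int, decimals: int = 0) -> float | None:
        return round_half_up(100.0 * num / den, decimals) if den else None

    all_row = s.all
    total = int(all_row["total"])
    destab_indels = s.destabilizing(fs) + s.destabilizing(inf)
    out = {
        "total_destabilizing": s.destabilizing(),
        "nonsense_destabilizing_pct": pct(s.destabilizing(ns),
                                          int(s.row(ns)["total"]), 1),
        "frameshift_destabilizing_pct": pct(s.destabilizing(fs),
                                            int(s.row(fs)["total"]), 1),
        "inframe_destabilizing_pct": pct(s.destabilizing(inf),
                                         int(s.row(inf)["total"]), 1),
        "inframe_not_destabilizing_pct": pct(int(s.row(inf)["no"]),
                                             int(s.row(inf)["total"]), 1),
        # dominant share among the destabilizing calls of each class
        "nonsense_dominant_share_pct": pct(int(s.row(ns)["dominant"]),
                                           s.destabilizing(ns)),
        "frameshift_dominant_share_pct": pct(int(s.row(fs)["dominant"]),
                                             s.destabilizing(fs)),
        "indel_dominant_share_pct": pct(
            int(s.row(fs)["dominant"] + s.row(inf)["dominant"]), destab_indels),
        # dominant share of each class total
        "nonsense_dominant_of_class_pct": pct(int(s.row(ns)["dominant"]),
                                              int(s.row(ns)["total"])),
        "frameshift_dominant_of_class_pct": pct(int(s.row(fs)["dominant"]),
                                                int(s.row(fs)["total"])),
        "hold_total": int(all_row["hold"]),
        "hold_pct": pct(int(all_row["hold"]), total),
        "aggregation_prone_total": int(all_row["dominant"]),
        "aggregation_prone_pct": pct(int(all_row["dominant"]), total),
    }
    if hold_reasons is not None:
        reasons = list(hold_reasons)
        n_nostruct = sum(1 for h in reasons if h is HoldReason.NO_STRUCTURE)
        out["hold_no_structure_total"] = n_nostruct
        out["hold_other_total"] = len(reasons) - n_nostruct
        out["hold_no_structure_share_pct"] = pct(n_nostruct, len(reasons))
        out["hold_no_structure_of_total_pct"] = pct(n_nostruct, total)
    return out
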