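"""Corpus-level aggregation: top-k tables and the yearly donation trend.

Mirrors the summary views a donation-mining study reports: most frequent
donors, donor-affiliation pairs, donating organizations, antibody names and
journals, and donations per year normalized per 1000 articles to factor out
the growth of the article base itself.  Counting is raw by default — "Keith
Gull" and "K. Gull" are distinct keys — with an optional initials-folding
normalizer for reporting only, never inside extraction.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .rule_extractor import DonationRecord

__all__ = [
    "TrendPoint",
    "TOP_K_KEYS",
    "top_k",
    "yearly_trend",
    "fold_initials",
    "plot_trend",
]

TOP_K_KEYS = ("donor", "donor_affiliation", "organization", "antibody", "journal")

_INITIALS_RE = re.compile(r"^([A-Z])\.\s+(.+)$")


def fold_initials(name: str) -> str:
    """Reporting-time normalizer: "K. Gull" -> "k gull" key form."""
    m = _INITIALS_RE.match(name.strip())
    if m:
        return f"{m.group(1).lower()} {m.group(2).lower()}"
    return name.strip().lower()


def _key_values(record: DonationRecord, key: str) -> Optional[str]:
    if key == "donor":
        return record.donor
    if key == "donor_affiliation":
        if record.donor and record.affiliation:
            return f"{record.donor} | {record.affiliation}"
        return None
    if key == "organization":
        return record.affiliation
    if key == "antibody":
        return record.antibody
    if key == "journal":
        return record.journal
    raise ValueError(f"unknown top-k key: {key!r} (expected one of {TOP_K_KEYS})")


def top_k(
    records: Iterable[DonationRecord],
    key: str,
    k: Optional[int] = 5,
    normalize_names: bool = False,
) -> list[tuple[str, int]]:
    """Ranked (value, count) list for a key, ties broken lexicographically."""
    if key not in TOP_K_KEYS:
        raise ValueError(f"unknown top-k key: {key!r} (expected one of {TOP_K_KEYS})")
    counts: Counter[str] = Counter()
    for record in records:
        value = _key_values(record, key)
        if value is None:
            continue
        if normalize_names and key in ("donor", "donor_affiliation"):
            value = fold_initials(value)
        counts[value] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked if k is None else ranked[:k]


@dataclass(frozen=True)
class TrendPoint:
    """Donation count for one year, normalized per 1000 published articles."""

    year: int
    donations: int
    corpus_size: Optional[int]
    normalized: Optional[float]


def yearly_trend(
    records: Iterable[DonationRecord],
    corpus_counts: Mapping[int, int],
) -> list[TrendPoint]:
    """One point per year present in the records, ascending.

    ``normalized = donations / corpus_size * 1000``; years absent from
    ``corpus_counts`` (or with zero size) yield a point with ``normalized``
    set to ``None``.  Records without a year are ignored.
    """
    by_year: Counter[int] = Counter()
    for record in records:
        if record.year is not None:
            by_year[record.year] += 1
    points = []
    for year in sorted(by_year):
        donations = by_year[year]
        size = corpus_counts.get(year)
        if size:
            normalized = donations / size * 1000.0
        else:
            normalized = None
        points.append(TrendPoint(year, donations, size, normalized))
    return points


def plot_trend(points: Sequence[TrendPoint], path: str) -> None:
    """Write a two-axis PNG of counts and normalized rates (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    years = [p.year for p in points]
    fig, ax1 = plt.subplots(figsize=(7, 4))
    ax1.bar(years, [p.donations for p in points], color="#4878a8",
            label="donations")
    ax1.set_xlabel("year")
    ax1.set_ylabel("donations")
    ax2 = ax1.twinx()
    ax2.plot(
        years,
        [p.normalized if p.normalized is not None else float("nan") for p in points],
        color="#b04030",
        marker="o",
        label="per 1000 articles",
    )
    ax2.set_ylabel("donations per 1000 articles")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
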