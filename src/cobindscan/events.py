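"""Classification of two TFs' ChIP-seq peaks into solo and co-occupied binding events.

Two transcription factors A and B are said to co-occupy a genomic region when
a peak of A and a peak of B overlap reciprocally: the overlap covers at least
``min_frac`` (default 30%) of *each* peak. Every peak is then assigned to one
of three binding-event categories — ``A_only``, ``co_occupied`` or ``B_only``
— and a co-occupied peak records its best reciprocal partner. Peak summits
represent the binding sites and are used downstream for window centering;
the overlap itself is computed on the full peak intervals.

Coordinates follow the BED convention throughout: 0-based, half-open.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORY_A_ONLY = "A_only"
CATEGORY_B_ONLY = "B_only"
CATEGORY_CO = "co_occupied"


class ValidationError(ValueError):
    """Raised for malformed inputs (bad intervals, duplicate names, bad config)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """A called binding interval with a summit (absolute 0-based position)."""

    chrom: str
    start: int
    end: int
    summit: int
    score: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"malformed peak {self.name!r} {self.chrom}:{self.start}-{self.end}"
            )
        if not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"summit {self.summit} of peak {self.name!r} outside "
                f"[{self.start}, {self.end})"
            )

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> tuple[float, float]:
    """Fraction of ``a`` covered by ``b`` and of ``b`` covered by ``a``.

    Returns ``(0.0, 0.0)`` for disjoint intervals or different chromosomes.
    """
    ov = a.overlap_bp(b)
    return ov / len(a), ov / len(b)


@dataclass
class EventTable:
    """Binding events for a TF pair: one record per input peak.

    ``df`` columns: chrom, start, end, summit, score, name, source_tf
    (``"A"``/``"B"``), category (``A_only``/``co_occupied``/``B_only``) and
    partner_name (empty string for solo events). A co-occupied region
    contributes two records, one from each source TF, because the two
    partners' peaks (and summits) are generally not at identical positions.
    """

    df: pd.DataFrame
    tf_a: str = "A"
    tf_b: str = "B"

    COLUMNS = (
        "chrom",
        "start",
        "end",
        "summit",
        "score",
        "name",
        "source_tf",
        "category",
        "partner_name",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"EventTable missing columns: {missing}")
        co = self.df["category"] == CATEGORY_CO
        if (co != (self.df["partner_name"] != "")).any():
            raise ValidationError("partner_name must be set iff category is co_occupied")

    def side(self, source_tf: str) -> pd.DataFrame:
        """Records from one source TF, in table order."""
        if source_tf not in ("A", "B"):
            raise ValidationError(f"source_tf must be 'A' or 'B', got {source_tf!r}")
        return self.df[self.df["source_tf"] == source_tf]

    def counts(self) -> dict[str, int]:
        return self.df["category"].value_counts().to_dict()

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, tf_a: str = "A", tf_b: str = "B") -> "EventTable":
        df = pd.read_csv(path, sep="\t", dtype={"name": str, "partner_name": str})
        df["partner_name"] = df["partner_name"].fillna("")
        return cls(df, tf_a=tf_a, tf_b=tf_b)


def _check_unique_names(peaks: list[Peak], label: str) -> None:
    names = [p.name for p in peaks]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicated peak identifiers in {label}: {dupes[:5]}")


def _best_partners(
    queries: list[Peak], others: list[Peak], min_frac: float
) -> list[Peak | None]:
    """For each query peak, its best reciprocal partner among ``others`` or None.

    Sweep over peaks sorted by start within each chromosome, maintaining an
    active set of candidate partners, so total work is near-linear in the
    number of peaks plus the number of genuinely overlapping pairs.

    Best = largest min(frac_query, frac_partner); ties broken by leftmost
    partner start, then partner end, then name (fully deterministic).
    """
    by_chrom: dict[str, list[Peak]] = {}
    for p in others:
        by_chrom.setdefault(p.chrom, []).append(p)
    for plist in by_chrom.values():
        plist.sort(key=lambda p: (p.start, p.end, p.name))

    order = sorted(range(len(queries)), key=lambda i: (queries[i].chrom, queries[i].start))
    result: list[Peak | None] = [None] * len(queries)

    cur_chrom = None
    active: list[Peak] = []
    next_idx = 0
    starts: list[int] = []
    for qi in order:
        q = queries[qi]
        if q.chrom != cur_chrom:
            cur_chrom = q.chrom
            pool = by_chrom.get(cur_chrom, [])
            starts = [p.start for p in pool]
            active = []
            next_idx = 0
        else:
            pool = by_chrom.get(cur_chrom, [])
        # admit partners whose start precedes the query's end
        hi = bisect.bisect_left(starts, q.end, lo=next_idx)
        active.extend(pool[next_idx:hi])
        next_idx = hi
        # retire partners that end at or before the query's start: they cannot
        # overlap this query nor any later one (starts are nondecreasing)
        active = [p for p in active if p.end > q.start]

        best_key = None
        best: Peak | None = None
        for p in active:
            fa, fb = overlap_fraction(q.interval, p.interval)
            if fa >= min_frac and fb >= min_frac:
                key = (-min(fa, fb), p.start, p.end, p.name)
                if best_key is None or key < best_key:
                    best_key = key
                    best = p
        result[qi] = best
    return result


def classify_events(
    peaks_a: list[Peak],
    peaks_b: list[Peak],
    min_frac: float = 0.30,
    tf_a: str = "A",
    tf_b: str = "B",
) -> EventTable:
    """Partition two peak sets into solo and co-occupied binding events.

    A peak is ``co_occupied`` iff some peak of the other TF overlaps it such
    that both overlap fractions are at least ``min_frac``; otherwise it is a
    solo (``A_only``/``B_only``) event. Output rows keep the input order:
    all A peaks first, then all B peaks. Either input may be empty.
    """
    if not (0 < min_frac <= 1):
        raise ValidationError(f"min_frac must be in (0, 1], got {min_frac}")
    _check_unique_names(peaks_a, "peaks_a")
    _check_unique_names(peaks_b, "peaks_b")

    partners_a = _best_partners(peaks_a, peaks_b, min_frac)
    partners_b = _best_partners(peaks_b, peaks_a, min_frac)

    rows = []
    for peaks, partners, src, solo_cat in (
        (peaks_a, partners_a, "A", CATEGORY_A_ONLY),
        (peaks_b, partners_b, "B", CATEGORY_B_ONLY),
    ):
        for p, partner in zip(peaks, partners):
            rows.append(
                (
                    p.chrom,
                    p.start,
                    p.end,
                    p.summit,
                    p.score,
                    p.name,
                    src,
                    CATEGORY_CO if partner is not None else solo_cat,
                    partner.name if partner is not None else "",
                )
            )
    df = pd.DataFrame(rows, columns=list(EventTable.COLUMNS))
    return EventTable(df, tf_a=tf_a, tf_b=tf_b)


# ---------------------------------------------------------------------------
# Peak file I/O (narrowPeak / BED)
# ---------------------------------------------------------------------------

def read_narrowpeak(path) -> list[Peak]:
    """Read an ENCODE narrowPeak (BED6+4) file.

    Column 10 is the summit offset from ``start``; a value of -1 (summit not
    called) falls back to the interval midpoint. Plain BED files with fewer
    than 10 columns are accepted the same way.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValidationError(f"{path}:{ln}: fewer than 3 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 and f[3] not in (".", "") else f"peak_{ln}"
            score = float(f[6]) if len(f) > 6 else (float(f[4]) if len(f) > 4 else 0.0)
            offset = int(f[9]) if len(f) > 9 else -1
            summit = start + offset if offset >= 0 else (start + end) // 2
            peaks.append(Peak(chrom, start, end, summit, score, name))
    return peaks


def write_narrowpeak(peaks: list[Peak], path) -> None:
    """Write peaks as narrowPeak; summit stored as an offset from start."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t"
                f"{p.score:g}\t-1\t-1\t{p.summit - p.start}\n"
            )
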