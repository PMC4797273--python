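"""Chromatin-feature quantification at binding events.

Signals (chromatin accessibility and histone marks) are measured as RPKM —
reads per kilobase of window per million mapped reads — in a small window
centered on each peak summit (default 100 bp), and log2-transformed with a
pseudocount for modeling. Wider 6-kb profiles binned at 100 bp summarize the
signal shape around summits per binding-event category. Sequence GC content
is computed on the same central window; CpG methylation is averaged over the
CpGs falling in the window (missing when none do); a chromatin-state
segmentation contributes the label of the state containing the summit,
one-hot encoded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EventTable, GenomicInterval, ValidationError
from .genome import InMemoryGenome, gc_content

logger = logging.getLogger(__name__)

#: the 11 histone channels (10 methylation/acetylation marks + variant H2A.Z)
HISTONE_MARKS = (
    "H2A.Z",
    "H3K4me1",
    "H3K4me2",
    "H3K4me3",
    "H3K9ac",
    "H3K9me3",
    "H3K27ac",
    "H3K27me3",
    "H3K36me3",
    "H3K79me2",
    "H4K20me1",
)
DNASE = "DNaseI"


# ---------------------------------------------------------------------------
# windows and elementary quantities
# ---------------------------------------------------------------------------

def window_around(
    summit: int, width: int = 100, chrom: str = "", chrom_length: int | None = None
) -> GenomicInterval:
    """The ``width``-bp window centered at a summit, clipped to the chromosome.

    ``width`` must be even and positive. Clipping at position 0 (and at
    ``chrom_length`` when given) is logged; a summit at or beyond the
    chromosome end is an error.
    """
    if width <= 0 or width % 2:
        raise ValidationError(f"window width must be even and positive, got {width}")
    if chrom_length is not None and summit >= chrom_length:
        raise ValidationError(
            f"summit {summit} beyond chromosome {chrom!r} end {chrom_length}"
        )
    start = summit - width // 2
    end = summit + width // 2
    if start < 0:
        logger.warning("window at %s:%d clipped at chromosome start", chrom, summit)
        start = 0
    if chrom_length is not None and end > chrom_length:
        logger.warning("window at %s:%d clipped at chromosome end", chrom, summit)
        end = chrom_length
    return GenomicInterval(chrom or "?", start, end)


def rpkm(count: float, window_bp: int, library_size: int) -> float:
    """Reads per kilobase of window per million mapped reads."""
    if window_bp <= 0:
        raise ValidationError(f"window_bp must be positive, got {window_bp}")
    if library_size <= 0:
        raise ValidationError(f"library_size must be positive, got {library_size}")
    return count / (window_bp / 1000.0) / (library_size / 1e6)


# ---------------------------------------------------------------------------
# read tracks
# ---------------------------------------------------------------------------

class ReadTrack:
    """Aligned-read intervals for one chromatin feature, plus library size.

    Reads are stored per chromosome as independently sorted start and end
    arrays, which is all that counting overlaps requires: the number of reads
    overlapping ``[s, e)`` by >= 1 bp is ``n - #(start >= e) - #(end <= s)``
    (the two excluded groups are disjoint since every read is non-empty).
    """

    def __init__(self, feature_name: str, library_size: int):
        if library_size <= 0:
            raise ValidationError("library_size must be a positive integer")
        self.feature_name = feature_name
        self.library_size = int(library_size)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._n_reads = 0

    @classmethod
    def from_arrays(
        cls,
        feature_name: str,
        reads: dict[str, tuple[np.ndarray, np.ndarray]],
        library_size: int | None = None,
    ) -> "ReadTrack":
        n_total = sum(len(s) for s, _ in reads.values())
        track = cls(feature_name, library_size if library_size is not None else n_total)
        for chrom, (starts, ends) in reads.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            if np.any(ends <= starts):
                raise ValidationError(f"empty read interval in track {feature_name!r}")
            track._starts[chrom] = np.sort(starts)
            track._ends[chrom] = np.sort(ends)
        track._n_reads = n_total
        if track.library_size < n_total:
            raise ValidationError("library_size smaller than number of stored reads")
        return track

    @classmethod
    def from_intervals(
        cls,
        feature_name: str,
        intervals,
        library_size: int | None = None,
    ) -> "ReadTrack":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        arrays = {
            c: (np.array([s for s, _ in v]), np.array([e for _, e in v]))
            for c, v in by_chrom.items()
        }
        return cls.from_arrays(feature_name, arrays, library_size)

    @classmethod
    def from_tagalign(cls, path, feature_name: str, library_size: int | None = None) -> "ReadTrack":
        """Read a tagAlign/BED file of aligned reads (columns chrom,start,end,...)."""
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
        )
        arrays = {
            str(c): (g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64))
            for c, g in df.groupby("chrom", sort=False)
        }
        return cls.from_arrays(feature_name, arrays, library_size)

    @property
    def n_reads(self) -> int:
        return self._n_reads

    def chromosomes(self) -> set[str]:
        return set(self._starts)

    def count_many(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray, mode: str = "overlap"
    ) -> np.ndarray:
        """Read counts for many windows on one chromosome (vectorized)."""
        starts = np.asarray(starts)
        ends = np.asarray(ends)
        if chrom not in self._starts:
            return np.zeros(len(starts), dtype=np.int64)
        rs, re = self._starts[chrom], self._ends[chrom]
        if mode == "overlap":
            n = len(rs)
            ge_end = n - np.searchsorted(rs, ends, side="left")
            le_start = np.searchsorted(re, starts, side="right")
            return n - ge_end - le_start
        if mode == "five_prime":
            return np.searchsorted(rs, ends, side="left") - np.searchsorted(
                rs, starts, side="left"
            )
        raise ValidationError(f"unknown count mode {mode!r}")

    def count(self, window: GenomicInterval, mode: str = "overlap") -> int:
        return int(
            self.count_many(
                window.chrom, np.array([window.start]), np.array([window.end]), mode
            )[0]
        )


def count_reads(track: ReadTrack, window: GenomicInterval, mode: str = "overlap") -> int:
    """Number of reads overlapping the window by >= 1 bp (or, in
    ``five_prime`` mode, whose start lies inside the window)."""
    return track.count(window, mode=mode)


class CoverageTrack:
    """Precomputed coverage (bedGraph) for one feature.

    In coverage mode the window statistic is the base-pair-weighted mean
    coverage over the window; no RPKM normalization applies (there is no
    library size), a documented mode difference from read tracks.
    """

    def __init__(self, feature_name: str, segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.feature_name = feature_name
        self._segments = {}
        for chrom, (starts, ends, values) in segments.items():
            order = np.argsort(starts)
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"overlapping bedGraph segments on {chrom}")
            self._segments[chrom] = (starts, ends, values.astype(float))

    @classmethod
    def from_bedgraph(cls, path, feature_name: str) -> "CoverageTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
            comment="t",  # skips "track ..." header lines
        )
        segs = {
            str(c): (
                g["start"].to_numpy(np.int64),
                g["end"].to_numpy(np.int64),
                g["value"].to_numpy(float),
            )
            for c, g in df.groupby("chrom", sort=False)
        }
        return cls(feature_name, segs)

    def mean_coverage(self, window: GenomicInterval) -> float:
        if window.chrom not in self._segments:
            return 0.0
        starts, ends, values = self._segments[window.chrom]
        lo = np.searchsorted(ends, window.start, side="right")
        hi = np.searchsorted(starts, window.end, side="left")
        total = 0.0
        for i in range(lo, hi):
            ov = min(ends[i], window.end) - max(starts[i], window.start)
            if ov > 0:
                total += ov * values[i]
        return total / len(window)


# ---------------------------------------------------------------------------
# CpG methylation and chromatin-state segmentation
# ---------------------------------------------------------------------------

class CpGTable:
    """Per-CpG methylation beta values (fractions in [0, 1])."""

    def __init__(self, entries: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._entries = {}
        for chrom, (pos, beta) in entries.items():
            pos = np.asarray(pos, dtype=np.int64)
            beta = np.asarray(beta, dtype=float)
            order = np.argsort(pos)
            pos, beta = pos[order], beta[order]
            if len(np.unique(pos)) != len(pos):
                raise ValidationError(f"duplicate CpG positions on {chrom}")
            if np.any((beta < 0) | (beta > 1)):
                raise ValidationError(f"beta values outside [0, 1] on {chrom}")
            self._entries[chrom] = (pos, beta)

    @classmethod
    def read_tsv(cls, path) -> "CpGTable":
        df = pd.read_csv(path, sep="\t")
        if not {"chrom", "position", "beta"} <= set(df.columns):
            df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "position", "beta"])
        return cls(
            {
                str(c): (g["position"].to_numpy(np.int64), g["beta"].to_numpy(float))
                for c, g in df.groupby("chrom", sort=False)
            }
        )

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tposition\tbeta\n")
            for chrom in self._entries:
                pos, beta = self._entries[chrom]
                for p, b in zip(pos, beta):
                    fh.write(f"{chrom}\t{p}\t{b:.6g}\n")

    def betas_in(self, window: GenomicInterval) -> np.ndarray:
        if window.chrom not in self._entries:
            return np.empty(0)
        pos, beta = self._entries[window.chrom]
        lo = np.searchsorted(pos, window.start, side="left")
        hi = np.searchsorted(pos, window.end, side="left")
        return beta[lo:hi]


def methylation_level(cpgs: CpGTable, window: GenomicInterval) -> float:
    """Mean beta over CpGs inside the window; NaN when no CpG maps there.

    Binding sites without a CpG carry no methylation measurement and are
    excluded from methylation-based models rather than imputed.
    """
    betas = cpgs.betas_in(window)
    if len(betas) == 0:
        return math.nan
    return float(np.mean(betas))


class Segmentation:
    """Non-overlapping labeled intervals (e.g. a 15-state ChromHMM segmentation)."""

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray, list[str]]],
                 states: list[str] | None = None):
        self._intervals = {}
        seen: set[str] = set()
        for chrom, (starts, ends, labels) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            labels = list(labels)
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            labels = [labels[i] for i in order]
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"overlapping segmentation intervals on {chrom}")
            self._intervals[chrom] = (starts, ends, labels)
            seen.update(labels)
        self.states = list(states) if states is not None else sorted(seen)
        missing = seen - set(self.states)
        if missing:
            raise ValidationError(f"segmentation labels outside state alphabet: {missing}")

    @classmethod
    def read_bed(cls, path, states: list[str] | None = None) -> "Segmentation":
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "state"],
        )
        return cls(
            {
                str(c): (
                    g["start"].to_numpy(np.int64),
                    g["end"].to_numpy(np.int64),
                    g["state"].astype(str).tolist(),
                )
                for c, g in df.groupby("chrom", sort=False)
            },
            states=states,
        )

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self._intervals:
                starts, ends, labels = self._intervals[chrom]
                for s, e, l in zip(starts, ends, labels):
                    fh.write(f"{chrom}\t{s}\t{e}\t{l}\n")

    def label_at(self, chrom: str, position: int) -> str | None:
        if chrom not in self._intervals:
            return None
        starts, ends, labels = self._intervals[chrom]
        i = np.searchsorted(starts, position, side="right") - 1
        if i >= 0 and position < ends[i]:
            return labels[i]
        return None


def state_at(seg: Segmentation, chrom: str, summit: int) -> tuple[str | None, np.ndarray]:
    """State label containing the summit (half-open intervals) and its one-hot
    encoding over the segmentation's state alphabet; a gap yields (None, zeros)."""
    label = seg.label_at(chrom, summit)
    onehot = np.zeros(len(seg.states))
    if label is not None:
        onehot[seg.states.index(label)] = 1.0
    return label, onehot


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Sites x features with binary labels (1 = co-occupied, 0 = solo)."""

    site_ids: np.ndarray
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray
    missing_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != (len(self.site_ids), len(self.feature_names)):
            raise ValidationError("FeatureMatrix shape mismatch")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValidationError("labels must be binary")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValidationError("non-finite values outside the missing mask")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def select_features(self, names: list[str]) -> "FeatureMatrix":
        idx = []
        for n in names:
            if n not in self.feature_names:
                raise ValidationError(f"feature {n!r} not in matrix ({self.feature_names})")
            idx.append(self.feature_names.index(n))
        return FeatureMatrix(
            self.site_ids, list(names), self.values[:, idx], self.labels,
            self.missing_mask[:, idx],
        )

    def subset_rows(self, mask_or_index) -> "FeatureMatrix":
        return FeatureMatrix(
            self.site_ids[mask_or_index],
            self.feature_names,
            self.values[mask_or_index],
            self.labels[mask_or_index],
            self.missing_mask[mask_or_index],
        )

    def drop_missing_rows(self) -> "FeatureMatrix":
        keep = ~self.missing_mask.any(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d rows with missing feature values", dropped)
        return self.subset_rows(keep)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "site_id", self.site_ids)
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        feats = [c for c in df.columns if c not in ("site_id", "label")]
        return cls(
            df["site_id"].to_numpy(object),
            feats,
            df[feats].to_numpy(float),
            df["label"].to_numpy(int),
        )


def resolve_feature_set(available: list[str], spec: str) -> list[str]:
    """Expand a feature-set name (``all``, ``dnase``, ``hms``, ``gc``,
    ``dnase+gc``, ``hms+gc``, a single mark, or comma-separated names)."""
    hms = [f for f in available if f in HISTONE_MARKS]
    groups = {
        "all": [f for f in available if f == DNASE or f in HISTONE_MARKS or f == "GC"],
        "dnase": [DNASE],
        "hms": hms,
        "gc": ["GC"],
        "methylation": ["methylation"],
        "state": [f for f in available if f.startswith("state_")],
    }
    parts: list[str] = []
    for token in spec.split("+"):
        token = token.strip()
        if token in groups:
            parts.extend(groups[token])
        elif token in available:
            parts.append(token)
        else:
            for sub in token.split(","):
                sub = sub.strip()
                if sub not in available:
                    raise ValidationError(f"unknown feature or set {sub!r}")
                parts.append(sub)
    out = []
    for p in parts:  # dedupe, keep order
        if p not in out:
            out.append(p)
    missing = [p for p in out if p not in available]
    if missing:
        raise ValidationError(f"features not present in matrix: {missing}")
    return out


def extract_features(
    events: EventTable,
    tracks: list,
    genome: InMemoryGenome | None = None,
    cpgs: CpGTable | None = None,
    seg: Segmentation | None = None,
    side: str = "A",
    window_bp: int = 100,
    pseudocount: float = 1.0,
    count_mode: str = "overlap",
    drop_missing_methylation: bool = True,
) -> FeatureMatrix:
    """Build the sites x features matrix for one contrast side.

    Rows are the event records of ``side`` (solo events of that TF plus its
    co-occupied records), labeled 1 for co-occupied and 0 for solo. Columns
    are log2(RPKM + pseudocount) per read track (mean coverage for coverage
    tracks), GC content of the window when a genome is given, the mean CpG
    beta when a CpG table is given, and a one-hot chromatin state when a
    segmentation is given. When methylation is requested, rows without any
    CpG in the window are dropped (they carry no measurement).
    """
    records = events.side(side).reset_index(drop=True)
    n = len(records)
    chrom_sizes = genome.chrom_sizes if genome is not None else {}

    windows = []
    for rec in records.itertuples():
        windows.append(
            window_around(
                int(rec.summit), window_bp, chrom=rec.chrom,
                chrom_length=chrom_sizes.get(rec.chrom),
            )
        )

    cols: dict[str, np.ndarray] = {}
    for track in tracks:
        vals = np.full(n, np.nan)
        if isinstance(track, CoverageTrack):
            for i, w in enumerate(windows):
                vals[i] = math.log2(track.mean_coverage(w) + pseudocount)
        else:
            by_chrom: dict[str, list[int]] = {}
            for i, w in enumerate(windows):
                by_chrom.setdefault(w.chrom, []).append(i)
            for chrom, idx in by_chrom.items():
                if chrom not in track.chromosomes() and track.n_reads > 0:
                    # a track that covers other chromosomes but not this one
                    # carries no measurement here; an entirely empty track
                    # simply counts zero everywhere
                    logger.warning(
                        "track %s has no chromosome %s; %d rows flagged missing",
                        track.feature_name, chrom, len(idx),
                    )
                    continue
                s = np.array([windows[i].start for i in idx])
                e = np.array([windows[i].end for i in idx])
                counts = track.count_many(chrom, s, e, mode=count_mode)
                for j, i in enumerate(idx):
                    r = rpkm(counts[j], len(windows[i]), track.library_size)
                    vals[i] = math.log2(r + pseudocount)
        cols[track.feature_name] = vals

    if genome is not None:
        cols["GC"] = np.array([gc_content(genome.fetch(w.chrom, w.start, w.end)) for w in windows])
    if cpgs is not None:
        cols["methylation"] = np.array([methylation_level(cpgs, w) for w in windows])
    if seg is not None:
        onehots = np.zeros((n, len(seg.states)))
        gaps = np.zeros(n, dtype=bool)
        for i, rec in enumerate(records.itertuples()):
            label, oh = state_at(seg, rec.chrom, int(rec.summit))
            onehots[i] = oh
            gaps[i] = label is None

    feature_names = list(cols)
    values = np.column_stack([cols[f] for f in feature_names]) if feature_names else np.zeros((n, 0))
    mask = ~np.isfinite(values)
    if seg is not None:
        state_names = [f"state_{s}" for s in seg.states]
        values = np.column_stack([values, onehots])
        mask = np.column_stack([mask, np.tile(gaps[:, None], (1, len(state_names)))])
        feature_names = feature_names + state_names

    values = values.copy()
    values[mask] = np.nan
    labels = (records["category"] == "co_occupied").astype(int).to_numpy()
    matrix = FeatureMatrix(
        records["name"].to_numpy(object), feature_names, values, labels, mask
    )
    if cpgs is not None and drop_missing_methylation:
        j = matrix.feature_names.index("methylation")
        keep = ~matrix.missing_mask[:, j]
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d sites without CpG coverage", dropped)
        matrix = matrix.subset_rows(keep)
    return matrix


# ---------------------------------------------------------------------------
# binned profiles
# ---------------------------------------------------------------------------

@dataclass
class ProfileMatrix:
    """Per-category mean RPKM in fixed bins around summits for one feature."""

    feature_name: str
    bin_centers: np.ndarray           # offsets in bp relative to summit
    categories: list[str]
    mean_rpkm: np.ndarray             # categories x bins
    n_sites: np.ndarray               # categories x bins (clipped bins excluded)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, cat in enumerate(self.categories):
            for bi, off in enumerate(self.bin_centers):
                rows.append(
                    (self.feature_name, cat, int(off),
                     self.mean_rpkm[ci, bi], int(self.n_sites[ci, bi]))
                )
        return pd.DataFrame(rows, columns=["feature", "category", "offset", "mean_rpkm", "n"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def aggregate_profile(
    events: EventTable,
    track: ReadTrack,
    span: int = 6000,
    bin_bp: int = 100,
    chrom_sizes: dict[str, int] | None = None,
    side: str | None = None,
    count_mode: str = "overlap",
) -> ProfileMatrix:
    """Mean binned RPKM around summits, per binding-event category.

    The ``span``-bp region centered at each summit is cut into ``bin_bp``
    bins; each bin's count is converted to RPKM with the bin width as the
    region length. Bins extending past a chromosome edge are excluded from
    that site's contribution (per-bin site counts record this).
    """
    if span % bin_bp:
        raise ValidationError("span must be divisible by bin_bp")
    records = events.df if side is None else events.side(side)
    nbins = span // bin_bp
    offsets = np.arange(nbins) * bin_bp - span // 2 + bin_bp // 2
    categories = sorted(records["category"].unique())
    sums = np.zeros((len(categories), nbins))
    counts = np.zeros((len(categories), nbins), dtype=int)
    cat_index = {c: i for i, c in enumerate(categories)}

    for rec in records.itertuples():
        left = int(rec.summit) - span // 2
        starts = left + np.arange(nbins) * bin_bp
        ends = starts + bin_bp
        size = (chrom_sizes or {}).get(rec.chrom)
        valid = starts >= 0
        if size is not None:
            valid &= ends <= size
        if not valid.any():
            continue
        c = track.count_many(rec.chrom, starts[valid], ends[valid], mode=count_mode)
        r = np.array([rpkm(x, bin_bp, track.library_size) for x in c])
        ci = cat_index[rec.category]
        sums[ci, valid] += r
        counts[ci, valid] += 1

    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return ProfileMatrix(track.feature_name, offsets, categories, means, counts)
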