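"""Synthetic ChIP-seq-like inputs with controlled co-occupancy structure.

The generator emulates everything the pipeline consumes: two peak sets with
a known partition into solo and co-occupied events, per-feature read tracks
whose 100-bp window counts follow a negative-binomial law with configured
log2 effect sizes between event classes, a genome sequence with GC-biased
bases at binding windows, a sparse CpG methylation table with class-dependent
beta means, and a discrete chromatin-state segmentation whose "active" states
are preferentially assigned to co-occupied windows.

Construction guarantees, not probabilistic tendencies:

* solo peaks are placed in disjoint slots and overlap nothing, so they can
  never qualify as co-occupied;
* co-occupied partners share the peak width and their summit offset is
  clamped so the reciprocal-overlap fraction is >= 30% exactly — the truth
  labels are exact;
* signal reads for a co-occupied pair are placed so that each read overlaps
  both partners' central windows (possible whenever the summit offset allows
  it), so both windows observe the same negative-binomial count and the
  configured effect size is recovered without bleed-through corrections.

Background reads are uniform; there is no mappability, copy-number or strand
structure — deliberate simplifications documented in the methods notes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .events import CATEGORY_A_ONLY, CATEGORY_B_ONLY, CATEGORY_CO, EventTable, Peak, \
    ValidationError, read_narrowpeak, write_narrowpeak
from .features import CpGTable, DNASE, ReadTrack, Segmentation
from .genome import InMemoryGenome, load_fasta, write_fasta

import pandas as pd

#: default channels: accessibility + the 11 histone channels; effects emulate
#: the usual enrichment direction at co-occupied sites (active marks up,
#: the repressive mark down, the rest unchanged)
ACTIVE_MARKS = (DNASE, "H2A.Z", "H3K4me2", "H3K4me3", "H3K9ac", "H3K27ac")
NEUTRAL_MARKS = ("H3K4me1", "H3K36me3", "H4K20me1", "H3K79me2", "H3K9me3")
REPRESSIVE_MARKS = ("H3K27me3",)


@dataclass(frozen=True)
class FeatureTrackSpec:
    """One simulated signal channel.

    ``baseline_mu`` is the mean read count in a solo site's central window;
    co-occupied windows have mean ``baseline_mu * 2**log2_effect``. The count
    law is negative binomial with size parameter ``dispersion`` (variance
    mu + mu^2/dispersion); ``dispersion=None`` gives the Poisson limit.
    ``background_reads`` uniform reads are added genome-wide.
    """

    name: str
    baseline_mu: float = 20.0
    log2_effect: float = 0.0
    dispersion: float | None = 10.0
    background_reads: int = 5000

    def __post_init__(self) -> None:
        if self.baseline_mu <= 0:
            raise ValidationError(f"baseline_mu must be positive for {self.name}")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValidationError(f"dispersion must be positive for {self.name}")


def default_features(
    effect_active: float = 1.5,
    effect_neutral: float = 0.0,
    effect_repressive: float = -0.5,
) -> list[FeatureTrackSpec]:
    feats = [FeatureTrackSpec(n, log2_effect=effect_active) for n in ACTIVE_MARKS]
    feats += [FeatureTrackSpec(n, log2_effect=effect_neutral) for n in NEUTRAL_MARKS]
    feats += [FeatureTrackSpec(n, log2_effect=effect_repressive) for n in REPRESSIVE_MARKS]
    return feats


@dataclass(frozen=True)
class SyntheticConfig:
    chrom_sizes: dict = field(default_factory=lambda: {"chrS1": 1_500_000, "chrS2": 1_500_000})
    n_a_only: int = 500
    n_b_only: int = 500
    n_co: int = 500
    peak_width_bp: int = 300
    summit_jitter_bp: float = 60.0
    features: tuple = field(default_factory=lambda: tuple(default_features()))
    read_length: int = 36
    window_bp: int = 100
    gc_background: float = 0.41
    gc_solo: float = 0.45
    gc_co: float = 0.55
    cpg_per_kb: float = 10.0
    beta_background: float = 0.75
    beta_solo: float = 0.60
    beta_co: float = 0.25
    beta_concentration: float = 10.0
    n_states: int = 15
    n_active_states: int = 4
    p_active_co: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_a_only, self.n_b_only, self.n_co) < 0:
            raise ValidationError("event counts must be nonnegative")
        for g in (self.gc_background, self.gc_solo, self.gc_co):
            if not (0 < g < 1):
                raise ValidationError("GC probabilities must be in (0, 1)")
        if self.peak_width_bp < self.window_bp:
            raise ValidationError("peak width must be at least the window width")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate feature names in config")

    @classmethod
    def null(cls, **overrides) -> "SyntheticConfig":
        """A configuration with no class differences on any channel."""
        base = cls(**overrides) if overrides else cls()
        return dataclasses.replace(
            base,
            features=tuple(
                dataclasses.replace(f, log2_effect=0.0) for f in base.features
            ),
            gc_co=base.gc_solo,
            beta_co=base.beta_solo,
            p_active_co=0.0,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["features"] = [dataclasses.asdict(f) for f in self.features]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["features"] = tuple(FeatureTrackSpec(**f) for f in d.get("features", []))
        d["chrom_sizes"] = {str(k): int(v) for k, v in d["chrom_sizes"].items()}
        return cls(**d)


@dataclass
class SyntheticCell:
    config: SyntheticConfig
    peaks_a: list
    peaks_b: list
    tracks: dict              # feature name -> ReadTrack
    genome: InMemoryGenome
    cpgs: CpGTable
    segmentation: Segmentation
    truth: EventTable


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def _place_slots(rng, chrom_sizes: dict, widths: list[int], max_retries: int = 20):
    """Place disjoint slots (>=1 bp apart) uniformly across chromosomes.

    Returns a list of (chrom, start) in the order of ``widths``. Raises when
    placement is infeasible after bounded retries.
    """
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    if sum(widths) > 0.5 * sizes.sum():
        raise ValidationError(
            "total slot footprint exceeds 50% of the genome; use a larger genome"
        )
    for _ in range(max_retries):
        assignment = rng.choice(len(chroms), size=len(widths), p=sizes / sizes.sum())
        ok = True
        for ci in range(len(chroms)):
            idx = np.flatnonzero(assignment == ci)
            need = sum(widths[i] for i in idx) + max(0, len(idx) - 1)
            if need > chrom_sizes[chroms[ci]]:
                ok = False
                break
        if ok:
            break
    else:
        raise ValidationError("could not place peaks; use a larger genome")

    placements: list[tuple[str, int] | None] = [None] * len(widths)
    for ci, chrom in enumerate(chroms):
        idx = list(np.flatnonzero(assignment == ci))
        rng.shuffle(idx)
        total_w = sum(widths[i] for i in idx)
        slack = chrom_sizes[chrom] - total_w - max(0, len(idx) - 1)
        offsets = np.sort(rng.integers(0, slack + 1, size=len(idx)))
        pos = 0
        for k, i in enumerate(idx):
            start = int(offsets[k]) + pos + k  # k enforced 1-bp gaps so far
            placements[i] = (chrom, start)
            pos += widths[i]
    return placements


def _nbinom(rng, mu: float, dispersion: float | None, size: int) -> np.ndarray:
    if size == 0:
        return np.zeros(0, dtype=np.int64)
    if dispersion is None:
        return rng.poisson(mu, size=size)
    lam = rng.gamma(shape=dispersion, scale=mu / dispersion, size=size)
    return rng.poisson(lam)


def _beta(rng, mean: float, conc: float, size: int) -> np.ndarray:
    return rng.beta(mean * conc, (1 - mean) * conc, size=size)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_cell(config: SyntheticConfig) -> SyntheticCell:
    """Generate one synthetic cell: peaks, read tracks, genome, CpGs, states."""
    rng = np.random.default_rng(config.seed)
    w = config.peak_width_bp
    half_win = config.window_bp // 2
    read_len = config.read_length
    # padding keeps a site's signal reads inside its own slot
    pad = max(0, half_win + read_len - w // 2) + 1

    kinds = (["A"] * config.n_a_only + ["B"] * config.n_b_only + ["co"] * config.n_co)
    widths = [w + 2 * pad if k != "co" else 2 * w + 2 * pad for k in kinds]
    placements = _place_slots(rng, config.chrom_sizes, widths)

    # summit offset clamp guaranteeing >= 30% reciprocal overlap for equal widths
    d_max = int(np.floor(0.7 * w))
    while (w - d_max) / w < 0.30:
        d_max -= 1

    peaks_a: list[dict] = []
    peaks_b: list[dict] = []
    for (chrom, slot_start), kind in zip(placements, kinds):
        if kind == "co":
            d = int(np.clip(round(rng.normal(0.0, config.summit_jitter_bp)), -d_max, d_max))
            a_start = slot_start + pad + max(0, -d)
            b_start = a_start + d
            pid = len(peaks_a) + len(peaks_b)
            peaks_a.append(dict(chrom=chrom, start=a_start, category=CATEGORY_CO, pair=pid))
            peaks_b.append(dict(chrom=chrom, start=b_start, category=CATEGORY_CO, pair=pid))
        elif kind == "A":
            peaks_a.append(dict(chrom=chrom, start=slot_start + pad,
                                category=CATEGORY_A_ONLY, pair=None))
        else:
            peaks_b.append(dict(chrom=chrom, start=slot_start + pad,
                                category=CATEGORY_B_ONLY, pair=None))

    for prefix, plist in (("peakA", peaks_a), ("peakB", peaks_b)):
        plist.sort(key=lambda p: (p["chrom"], p["start"]))
        for i, p in enumerate(plist):
            p["name"] = f"{prefix}_{i + 1:05d}"
            p["summit"] = p["start"] + w // 2

    pair_names: dict[int, dict[str, str]] = {}
    for side, plist in (("A", peaks_a), ("B", peaks_b)):
        for p in plist:
            if p["pair"] is not None:
                pair_names.setdefault(p["pair"], {})[side] = p["name"]

    def to_peak(p: dict) -> Peak:
        return Peak(p["chrom"], p["start"], p["start"] + w, p["summit"], 0.0, p["name"])

    peak_objs_a = [to_peak(p) for p in peaks_a]
    peak_objs_b = [to_peak(p) for p in peaks_b]

    rows = []
    for side, plist, solo_cat in (("A", peaks_a, CATEGORY_A_ONLY), ("B", peaks_b, CATEGORY_B_ONLY)):
        other = "B" if side == "A" else "A"
        for p in plist:
            partner = pair_names[p["pair"]][other] if p["pair"] is not None else ""
            rows.append((p["chrom"], p["start"], p["start"] + w, p["summit"], 0.0,
                         p["name"], side, p["category"], partner))
    truth = EventTable(pd.DataFrame(rows, columns=list(EventTable.COLUMNS)))

    # ---- signal sites: one count per solo window, one shared count per pair
    solo_sites = [p for p in peaks_a + peaks_b if p["pair"] is None]
    pairs: dict[int, list[dict]] = {}
    for p in peaks_a + peaks_b:
        if p["pair"] is not None:
            pairs.setdefault(p["pair"], []).append(p)

    tracks: dict[str, ReadTrack] = {}
    chrom_list = list(config.chrom_sizes)
    chrom_sizes_arr = np.array([config.chrom_sizes[c] for c in chrom_list], dtype=float)
    for fs in config.features:
        mu_co = fs.baseline_mu * 2.0 ** fs.log2_effect
        solo_counts = _nbinom(rng, fs.baseline_mu, fs.dispersion, len(solo_sites))
        pair_ids = sorted(pairs)
        pair_counts = _nbinom(rng, mu_co, fs.dispersion, len(pair_ids))

        chroms_out: dict[str, list[np.ndarray]] = {c: [] for c in chrom_list}

        def emit(chrom: str, lo: int, hi: int, count: int) -> None:
            if count > 0:
                chroms_out[chrom].append(rng.integers(lo, hi + 1, size=count))

        for p, c in zip(solo_sites, solo_counts):
            s = p["summit"]
            emit(p["chrom"], s - half_win - read_len + 1, s + half_win - 1, int(c))
        for pid, c in zip(pair_ids, pair_counts):
            members = pairs[pid]
            summits = [m["summit"] for m in members]
            chrom = members[0]["chrom"]
            lo = max(summits) - half_win - read_len + 1
            hi = min(summits) + half_win - 1
            if lo <= hi:
                # every read overlaps both partners' windows
                emit(chrom, lo, hi, int(c))
            else:
                # summits too far apart for shared reads: independent draws,
                # placement ranges are disjoint so there is no bleed-through
                extra = _nbinom(rng, mu_co, fs.dispersion, len(members) - 1)
                for m, cm in zip(members, [int(c)] + [int(x) for x in extra]):
                    s = m["summit"]
                    emit(m["chrom"], s - half_win - read_len + 1, s + half_win - 1, cm)

        bg_per_chrom = rng.multinomial(fs.background_reads, chrom_sizes_arr / chrom_sizes_arr.sum())
        for c, nbg in zip(chrom_list, bg_per_chrom):
            if nbg > 0:
                chroms_out[c].append(rng.integers(0, config.chrom_sizes[c] - read_len + 1, size=nbg))

        arrays = {}
        total = 0
        for c, parts in chroms_out.items():
            if not parts:
                continue
            starts = np.clip(np.concatenate(parts), 0, config.chrom_sizes[c] - read_len)
            arrays[c] = (starts, starts + read_len)
            total += len(starts)
        tracks[fs.name] = ReadTrack.from_arrays(fs.name, arrays, library_size=max(total, 1))

    # ---- genome sequence with GC-biased binding windows
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def draw_bases(gc: float, size: int) -> np.ndarray:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        return rng.choice(4, size=size, p=p).astype(np.uint8)

    seq_codes = {c: draw_bases(config.gc_background, config.chrom_sizes[c]) for c in chrom_list}
    solo_windows = [(p["chrom"], p["summit"] - half_win, p["summit"] + half_win)
                    for p in solo_sites]
    co_windows = []
    for pid in sorted(pairs):
        members = pairs[pid]
        summits = [m["summit"] for m in members]
        co_windows.append((members[0]["chrom"], min(summits) - half_win, max(summits) + half_win))
    for windows, gc in ((solo_windows, config.gc_solo), (co_windows, config.gc_co)):
        for chrom, lo, hi in windows:
            lo = max(lo, 0)
            hi = min(hi, config.chrom_sizes[chrom])
            seq_codes[chrom][lo:hi] = draw_bases(gc, hi - lo)
    genome = InMemoryGenome({c: bases[v].tobytes().decode() for c, v in seq_codes.items()})

    # ---- CpG methylation table
    cpg_entries = {}
    for c in chrom_list:
        size = config.chrom_sizes[c]
        n_cpg = rng.poisson(config.cpg_per_kb * size / 1000.0)
        pos = np.unique(rng.integers(0, size, size=n_cpg))
        beta = _beta(rng, config.beta_background, config.beta_concentration, len(pos))
        for windows, mean in ((solo_windows, config.beta_solo), (co_windows, config.beta_co)):
            for chrom, lo, hi in windows:
                if chrom != c:
                    continue
                i0, i1 = np.searchsorted(pos, [max(lo, 0), min(hi, size)])
                if i1 > i0:
                    beta[i0:i1] = _beta(rng, mean, config.beta_concentration, i1 - i0)
        cpg_entries[c] = (pos, beta)
    cpgs = CpGTable(cpg_entries)

    # ---- chromatin-state segmentation
    states = [f"E{i}" for i in range(1, config.n_states + 1)]
    seg_intervals = {}
    for c in chrom_list:
        size = config.chrom_sizes[c]
        n_est = max(8, int(2.5 * size / 1000) + 8)
        lengths = np.maximum(rng.exponential(1000.0, size=n_est).astype(np.int64), 200)
        while lengths.sum() < size:
            lengths = np.concatenate([lengths, np.maximum(
                rng.exponential(1000.0, size=n_est).astype(np.int64), 200)])
        ends = np.minimum(np.cumsum(lengths), size)
        keep = np.searchsorted(ends, size, side="left") + 1
        ends = ends[:keep]
        starts = np.r_[0, ends[:-1]]
        labels = [states[i] for i in rng.integers(0, config.n_states, size=len(starts))]
        seg_intervals[c] = (starts, ends, labels)
    segmentation = Segmentation(seg_intervals, states=states)
    # co-occupied windows preferentially carry low-index "active" states
    for pid in sorted(pairs):
        for m in pairs[pid]:
            if rng.random() < config.p_active_co:
                starts, ends, labels = segmentation._intervals[m["chrom"]]
                i = int(np.searchsorted(starts, m["summit"], side="right") - 1)
                if i >= 0 and m["summit"] < ends[i]:
                    labels[i] = states[int(rng.integers(0, config.n_active_states))]

    return SyntheticCell(config, peak_objs_a, peak_objs_b, tracks, genome, cpgs,
                         segmentation, truth)


# ---------------------------------------------------------------------------
# file round trip
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_cell(cell: SyntheticCell, out_dir) -> dict:
    """Write all standard-format files plus a manifest with checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    write_narrowpeak(cell.peaks_a, out / "peaks_a.narrowPeak")
    files["peaks_a"] = "peaks_a.narrowPeak"
    write_narrowpeak(cell.peaks_b, out / "peaks_b.narrowPeak")
    files["peaks_b"] = "peaks_b.narrowPeak"

    library_sizes = {}
    for name, track in cell.tracks.items():
        fname = f"reads_{name.replace('.', '')}.tagAlign"
        # starts and ends are stored sorted independently; pairing them in
        # sorted order reproduces the read set exactly for fixed-length reads
        # (the only kind this generator emits) and preserves overlap counts
        # in general
        with open(out / fname, "w") as fh:
            for chrom in sorted(track._starts):
                ss, ee = track._starts[chrom], track._ends[chrom]
                for s, e in zip(ss, ee):
                    fh.write(f"{chrom}\t{s}\t{e}\tN\t1000\t+\n")
        files[f"track:{name}"] = fname
        library_sizes[name] = track.library_size

    write_fasta(cell.genome, out / "genome.fa")
    files["genome"] = "genome.fa"
    cell.cpgs.write_tsv(out / "cpg.tsv")
    files["cpgs"] = "cpg.tsv"
    cell.segmentation.write_bed(out / "segmentation.bed")
    files["segmentation"] = "segmentation.bed"
    cell.truth.write_tsv(out / "truth_events.tsv")
    files["truth"] = "truth_events.tsv"

    manifest = {
        "config": cell.config.to_dict(),
        "files": files,
        "library_sizes": library_sizes,
        "checksums": {rel: _sha256(out / rel) for rel in files.values()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_cell(in_dir) -> SyntheticCell:
    """Re-read a written cell from its standard-format files."""
    src = Path(in_dir)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    config = SyntheticConfig.from_dict(manifest["config"])
    peaks_a = read_narrowpeak(src / manifest["files"]["peaks_a"])
    peaks_b = read_narrowpeak(src / manifest["files"]["peaks_b"])
    tracks = {}
    for key, fname in manifest["files"].items():
        if key.startswith("track:"):
            name = key.split(":", 1)[1]
            tracks[name] = ReadTrack.from_tagalign(
                src / fname, name, library_size=manifest["library_sizes"][name]
            )
    genome = load_fasta(src / manifest["files"]["genome"])
    cpgs = CpGTable.read_tsv(src / manifest["files"]["cpgs"])
    seg = Segmentation.read_bed(
        src / manifest["files"]["segmentation"],
        states=[f"E{i}" for i in range(1, config.n_states + 1)],
    )
    truth = EventTable.read_tsv(src / manifest["files"]["truth"])
    return SyntheticCell(config, peaks_a, peaks_b, tracks, genome, cpgs, seg, truth)
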