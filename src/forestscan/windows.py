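"""Sliding-window aggregation of variant importances and region calling.

Selection during domestication and breeding acts on haplotypes, not
single sites, so per-variant importance scores are summed in sliding
windows (5000 bp wide, 2500 bp offset by default, i.e. every position
beyond the first half-window is covered by exactly two windows). Windows
exceeding a threshold — either a fixed multiple of the mean window signal
or a per-window empirical permutation quantile — are merged into
candidate regions, which are then intersected with gene models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import sparse

from .matrix import FormatError


@dataclass
class WindowTrack:
    """Per-window importance sums and variant counts.

    ``windows`` columns: scaffold, start, end (0-based half-open),
    importance_sum, variant_count. Window starts are multiples of
    ``offset`` from position 0 of each scaffold; the last window may
    overhang the scaffold end.
    """

    windows: pd.DataFrame = field(repr=False)
    size: int = 5000
    offset: int = 2500

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class ThresholdSpec:
    """How above-background windows are identified.

    ``fixed_factor`` calls windows whose sum exceeds ``factor`` times the
    mean over eligible windows (those holding at least ``min_variants``
    variants — the same eligibility gates calling). ``permutation``
    shuffles the nonzero importances across their variant positions
    ``n_permutations`` times and calls windows exceeding their own
    empirical ``percentile`` quantile.
    """

    mode: str = "fixed_factor"
    factor: float = 2.5
    min_variants: int = 10
    n_permutations: int = 10000
    percentile: float = 99.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_factor", "permutation"):
            raise ValueError("mode must be fixed_factor or permutation")
        if self.factor <= 0:
            raise ValueError("factor must be positive")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


@dataclass
class RegionSet:
    """Merged above-threshold intervals, optionally with overlapping genes.

    ``regions`` columns: scaffold, start, end, n_windows,
    total_importance (sum of the member windows' sums; overlapping halves
    count twice) and, after :func:`regions_to_genes`, ``genes`` (comma
    joined ids).
    """

    regions: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def total_length(self) -> int:
        if self.regions.empty:
            return 0
        return int((self.regions["end"] - self.regions["start"]).sum())

    @property
    def n_windows(self) -> int:
        return int(self.regions["n_windows"].sum()) if len(self.regions) else 0


def _window_starts(length: int, offset: int) -> np.ndarray:
    return np.arange(0, length, offset, dtype=np.int64)


def build_track(
    dedup_importance: np.ndarray,
    variants: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    size: int = 5000,
    offset: int = 2500,
) -> WindowTrack:
    """Sum per-variant importance into sliding windows per scaffold.

    A variant at 1-based position ``pos`` contributes to every window with
    ``start <= pos - 1 < end``. With the default ``size = 2 * offset``
    each position from ``offset`` onward is covered by exactly two
    windows; the stripe before the first offset is covered once.
    """
    imp = np.asarray(dedup_importance, dtype=float)
    if len(imp) != len(variants):
        raise ValueError("importance vector length does not match variant table")
    frames = []
    for scaffold in sorted(scaffold_lengths):
        length = scaffold_lengths[scaffold]
        mask = (variants["scaffold"] == scaffold).to_numpy()
        pos0 = variants.loc[mask, "pos"].to_numpy(np.int64) - 1
        if pos0.size and pos0.max() >= length:
            bad = pos0.max() + 1
            raise ValueError(f"variant {scaffold}:{bad} beyond scaffold length {length}")
        v = imp[mask]
        order = np.argsort(pos0, kind="stable")
        pos0, v = pos0[order], v[order]
        csum = np.concatenate([[0.0], np.cumsum(v)])
        starts = _window_starts(length, offset)
        lo = np.searchsorted(pos0, starts, side="left")
        hi = np.searchsorted(pos0, starts + size, side="left")
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaffold,
                    "start": starts,
                    "end": starts + size,
                    "importance_sum": csum[hi] - csum[lo],
                    "variant_count": hi - lo,
                }
            )
        )
    unknown = set(variants["scaffold"]) - set(scaffold_lengths)
    if unknown:
        raise ValueError(f"variants on scaffolds without declared length: {sorted(unknown)}")
    windows = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["scaffold", "start", "end", "importance_sum", "variant_count"]
    )
    return WindowTrack(windows, size=size, offset=offset)


@dataclass
class ThresholdResult:
    """Called windows plus the threshold(s) that produced them."""

    called: np.ndarray = field(repr=False)  # boolean over track.windows rows
    eligible: np.ndarray = field(repr=False)
    threshold: float | np.ndarray | None = None

    @property
    def n_called(self) -> int:
        return int(self.called.sum())


def fixed_threshold(track: WindowTrack, spec: ThresholdSpec) -> ThresholdResult:
    """Call windows above ``factor`` x the mean eligible window sum.

    Strictly greater than the threshold; ties are not called.
    """
    sums = track.windows["importance_sum"].to_numpy(float)
    eligible = track.windows["variant_count"].to_numpy() >= spec.min_variants
    if not eligible.any():
        raise ValueError(
            f"no window holds >= {spec.min_variants} variants; lower min_variants"
        )
    threshold = spec.factor * float(sums[eligible].mean())
    called = eligible & (sums > threshold)
    return ThresholdResult(called=called, eligible=eligible, threshold=threshold)


def _window_membership(
    track: WindowTrack, variants: pd.DataFrame
) -> sparse.csr_matrix:
    """Sparse (n_windows x n_variants) indicator of variant-in-window."""
    win = track.windows
    # global index of the first window of each scaffold
    offsets: dict[str, int] = {}
    counts = win.groupby("scaffold", sort=False).size()
    running = 0
    for scaffold, c in counts.items():
        offsets[scaffold] = running
        running += int(c)
    n_per_scaffold = {s: int(c) for s, c in counts.items()}
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    pos0 = variants["pos"].to_numpy(np.int64) - 1
    scaffold_arr = variants["scaffold"].to_numpy()
    for scaffold in counts.index:
        mask = scaffold_arr == scaffold
        p = pos0[mask]
        vidx = np.nonzero(mask)[0]
        k_max = p // track.offset
        k_min = np.maximum(0, (p - track.size) // track.offset + 1)
        for shift in range(int((k_max - k_min).max()) + 1 if len(p) else 0):
            k = k_min + shift
            ok = (k <= k_max) & (k < n_per_scaffold[scaffold])
            rows.append(k[ok] + offsets[scaffold])
            cols.append(vidx[ok])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = np.empty(0, dtype=int)
        c = np.empty(0, dtype=int)
    return sparse.csr_matrix(
        (np.ones(len(r)), (r, c)), shape=(len(win), len(variants))
    )


def permutation_threshold(
    track: WindowTrack,
    dedup_importance: np.ndarray,
    variants: pd.DataFrame,
    spec: ThresholdSpec,
) -> ThresholdResult:
    """Empirical per-window null from shuffling detected importances.

    Each permutation redistributes the nonzero importance values
    uniformly over the nonzero-importance variant positions (positions
    stay fixed, values move); zero-importance variants stay zero. A
    window is called when its observed sum strictly exceeds the
    ``percentile``-th empirical order statistic of its own null sample,
    and it holds at least ``min_variants`` variants.
    """
    imp = np.asarray(dedup_importance, dtype=float)
    nz = np.nonzero(imp)[0]
    if nz.size == 0:
        raise ValueError("no nonzero importances to permute")
    rng = np.random.default_rng(spec.seed)
    A = _window_membership(track, variants)
    n_win = len(track.windows)
    order_idx = int(np.ceil(spec.percentile / 100.0 * spec.n_permutations)) - 1
    # accumulate null sums in chunks to bound memory
    null = np.empty((n_win, spec.n_permutations), dtype=np.float32)
    chunk = 200
    vals = imp[nz]
    base = np.zeros_like(imp)
    for start in range(0, spec.n_permutations, chunk):
        k = min(chunk, spec.n_permutations - start)
        P = np.zeros((len(imp), k))
        for j in range(k):
            P[nz, j] = rng.permutation(vals)
        null[:, start : start + k] = (A @ P).astype(np.float32)
    null.sort(axis=1)
    thresholds = null[:, order_idx].astype(float)
    sums = track.windows["importance_sum"].to_numpy(float)
    eligible = track.windows["variant_count"].to_numpy() >= spec.min_variants
    called = eligible & (sums.astype(np.float32) > thresholds.astype(np.float32))
    return ThresholdResult(called=called, eligible=eligible, threshold=thresholds)


def call_regions(track: WindowTrack, called: np.ndarray) -> RegionSet:
    """Merge called windows into regions by interval union.

    Overlapping or abutting called windows on one scaffold collapse into
    a single region; an isolated window becomes a region of window size.
    """
    win = track.windows.loc[np.asarray(called, dtype=bool)]
    rows = []
    for scaffold, grp in win.groupby("scaffold", sort=True):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        n = 0
        tot = 0.0
        for _, w in grp.iterrows():
            if cur_start is None:
                cur_start, cur_end, n, tot = w["start"], w["end"], 1, w["importance_sum"]
            elif w["start"] <= cur_end:
                cur_end = max(cur_end, w["end"])
                n += 1
                tot += w["importance_sum"]
            else:
                rows.append((scaffold, int(cur_start), int(cur_end), n, tot))
                cur_start, cur_end, n, tot = w["start"], w["end"], 1, w["importance_sum"]
        if cur_start is not None:
            rows.append((scaffold, int(cur_start), int(cur_end), n, tot))
    return RegionSet(
        pd.DataFrame(
            rows, columns=["scaffold", "start", "end", "n_windows", "total_importance"]
        )
    )


def read_genes(gff_path: str | Path, feature: str = "gene") -> pd.DataFrame:
    """Read gene features from GFF3 into 0-based half-open intervals.

    Returns columns ``gene_id, scaffold, start, end``. Lines that do not
    have nine tab-separated columns with integer coordinates raise a
    format error naming the line.
    """
    path = Path(gff_path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            raise FormatError(f"{path}:{lineno}: expected 9 tab-separated GFF columns")
        try:
            int(parts[3]), int(parts[4])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
    df = pr.read_gff3(str(path)).df
    df = df[df["Feature"] == feature]
    gene_id = df["ID"] if "ID" in df.columns else df.index.astype(str)
    return pd.DataFrame(
        {
            "gene_id": gene_id.to_numpy(),
            "scaffold": df["Chromosome"].astype(str).to_numpy(),
            "start": df["Start"].to_numpy(np.int64),
            "end": df["End"].to_numpy(np.int64),
        }
    ).reset_index(drop=True)


def overlapping_genes(
    regions: pd.DataFrame, genes: pd.DataFrame
) -> list[list[str]]:
    """Gene ids overlapping each region by >= 1 bp (half-open intervals)."""
    out: list[list[str]] = []
    for _, r in regions.iterrows():
        hit = genes[
            (genes["scaffold"] == r["scaffold"])
            & (genes["start"] < r["end"])
            & (genes["end"] > r["start"])
        ]
        out.append(hit["gene_id"].tolist())
    return out


def regions_to_genes(regions: RegionSet, gff_path: str | Path) -> RegionSet:
    """Attach overlapping gene ids to each region (comma-joined column)."""
    genes = read_genes(gff_path)
    df = regions.regions.copy()
    df["genes"] = [",".join(g) for g in overlapping_genes(df, genes)]
    return RegionSet(df)


def variants_to_genes(variants: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Gene id containing each variant ('' when intergenic)."""
    out = []
    for _, v in variants.iterrows():
        pos0 = v["pos"] - 1
        hit = genes[
            (genes["scaffold"] == v["scaffold"])
            & (genes["start"] <= pos0)
            & (genes["end"] > pos0)
        ]
        out.append(hit["gene_id"].iloc[0] if len(hit) else "")
    return pd.Series(out, index=variants.index)


def top_variants(
    models_importance: list[np.ndarray],
    dedup_importance: np.ndarray,
    variants: pd.DataFrame,
    k: int = 0,
) -> pd.DataFrame:
    """Union of each model's best variant plus the global top-k.

    Returns one row per selected variant with its coordinates, dedup
    importance and whether it was some model's best.
    """
    dedup = np.asarray(dedup_importance, dtype=float)
    best = {int(np.argmax(m)) for m in models_importance if len(m)}
    chosen = set(best)
    if k > 0:
        order = np.argsort(-dedup, kind="stable")
        chosen.update(int(i) for i in order[:k])
    idx = sorted(chosen)
    df = variants.iloc[idx][["scaffold", "pos"]].copy()
    df["dedup_importance"] = dedup[idx]
    df["model_best"] = [i in best for i in idx]
    return df.sort_values("dedup_importance", ascending=False).reset_index(drop=True)


def regions_to_bed(regions: RegionSet, path: str | Path) -> Path:
    """Write merged regions as BED6 (score = importance scaled to 0-1000)."""
    path = Path(path)
    df = regions.regions
    max_imp = df["total_importance"].max() if len(df) else 0.0
    with open(path, "w") as fh:
        for i, r in df.iterrows():
            score = int(round(1000 * r["total_importance"] / max_imp)) if max_imp > 0 else 0
            fh.write(
                f"{r['scaffold']}\t{r['start']}\t{r['end']}\tregion_{i}\t{score}\t.\n"
            )
    return path


def track_to_bedgraph(track: WindowTrack, path: str | Path) -> Path:
    """Write the window importance track as bedGraph for browser display."""
    path = Path(path)
    with open(path, "w") as fh:
        for _, w in track.windows.iterrows():
            fh.write(
                f"{w['scaffold']}\t{w['start']}\t{w['end']}\t{w['importance_sum']:.6g}\n"
            )
    return path
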