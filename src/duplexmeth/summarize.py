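"""Site filtering, per-site state fractions, and region/profile aggregation.

Sites are dropped when their double-stranded depth is below threshold (5x
by default), when the dyad overlaps a blacklisted interval, or when the
site accumulated multiple implausible call combinations (>= 2 by default).
Removal reasons are assigned in that fixed order -- depth, blacklist,
errors -- so each removed site is counted exactly once.

Per-site output reports the percentage of each duplex state over the
site's valid calls, together with the three strand-asymmetric groupings
(MC+CM, HC+CH, HM+MH).  Region means, shuffled backgrounds and binned
meta-profiles operate on those percentages; regions or bins that contain
no CpG site propagate as missing values, never as zero.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._tsv import read_table, write_table
from .model import ASYMMETRIC_GROUPS, STATE_ORDER

PCT_COLUMNS = [f"pct_{s}" for s in STATE_ORDER]
GROUP_COLUMNS = [f"pct_{g}" for g in ASYMMETRIC_GROUPS]
VALUE_COLUMNS = PCT_COLUMNS + GROUP_COLUMNS


def read_bed(path) -> pd.DataFrame:
    """Minimal BED reader (0-based half-open), with line numbers on errors."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from None
            if start < 0 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid BED interval {start}-{end}")
            rows.append((parts[0], start, end))
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def _as_regions(regions) -> pd.DataFrame:
    if isinstance(regions, pd.DataFrame):
        return regions[["contig", "start", "end"]].reset_index(drop=True)
    if isinstance(regions, (str,)) or hasattr(regions, "__fspath__"):
        return read_bed(regions)
    return pd.DataFrame(list(regions), columns=["contig", "start", "end"])


def filter_sites(sites: pd.DataFrame, min_depth: int = 5,
                 blacklist=None, max_errors: int = 1):
    """Apply the three site filters; returns (retained table, report).

    A dyad at pos0 occupies [pos0, pos0+2) for blacklist overlap.  The
    report counts removals per criterion in the order depth -> blacklist ->
    errors (first failing criterion claims the site).
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    trees: dict[str, IntervalTree] = {}
    if blacklist is not None:
        for row in _as_regions(blacklist).itertuples():
            if row.end > row.start:
                trees.setdefault(row.contig, IntervalTree()).addi(row.start, row.end)

    low_depth = sites["depth"] < min_depth
    if trees:
        in_blacklist = np.array([
            bool(trees.get(c)) and bool(trees[c].overlap(p, p + 2))
            for c, p in zip(sites["contig"], sites["pos0"])
        ])
    else:
        in_blacklist = np.zeros(len(sites), dtype=bool)
    too_many_errors = sites["implausible"] > max_errors

    reason = np.where(low_depth, "depth",
                      np.where(in_blacklist, "blacklist",
                               np.where(too_many_errors, "errors", "")))
    retained = sites[reason == ""].reset_index(drop=True)
    report = {
        "input": int(len(sites)),
        "removed_depth": int((reason == "depth").sum()),
        "removed_blacklist": int((reason == "blacklist").sum()),
        "removed_errors": int((reason == "errors").sum()),
        "retained": int(len(retained)),
    }
    return retained, report


def site_fractions(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-site state percentages (0-100) over valid (non-implausible) calls."""
    valid = sites[list(STATE_ORDER)].sum(axis=1).astype(float)
    out = sites[["contig", "pos0"]].copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        for name in STATE_ORDER:
            out[f"pct_{name}"] = np.where(valid > 0,
                                          100.0 * sites[name] / valid, np.nan)
    for gname, (s1, s2) in ASYMMETRIC_GROUPS.items():
        out[f"pct_{gname}"] = out[f"pct_{s1}"] + out[f"pct_{s2}"]
    out["depth"] = sites["depth"]
    return out


def region_means(fractions: pd.DataFrame, regions,
                 genome_sizes: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Mean state level per region over the CpG sites it contains.

    Regions with no CpG site yield missing values (NaN), not zero.  Regions
    extending beyond a known contig end are clipped with a warning.
    """
    regions = _as_regions(regions).copy()
    if genome_sizes:
        for row in regions.itertuples():
            size = genome_sizes.get(row.contig)
            if size is not None and row.end > size:
                warnings.warn(f"region {row.contig}:{row.start}-{row.end} "
                              f"clipped to contig end {size}")
                regions.loc[row.Index, "end"] = size
    records = []
    by_contig = dict(tuple(fractions.groupby("contig", sort=False)))
    for row in regions.itertuples():
        sub = by_contig.get(row.contig)
        if sub is not None:
            hit = sub[(sub["pos0"] >= row.start) & (sub["pos0"] < row.end)]
        else:
            hit = None
        values = ([hit[c].mean() for c in VALUE_COLUMNS]
                  if hit is not None and len(hit) else [np.nan] * len(VALUE_COLUMNS))
        n_sites = 0 if hit is None else int(len(hit))
        records.append((row.contig, row.start, row.end, n_sites, *values))
    return pd.DataFrame(records,
                        columns=["contig", "start", "end", "n_sites", *VALUE_COLUMNS])


def shuffled_background(fractions: pd.DataFrame, regions,
                        genome_sizes: Mapping[str, int],
                        n_shuffles: int, seed: int = 0) -> pd.DataFrame:
    """Background state levels from length-preserving random placement.

    Each shuffle relocates every region uniformly at random within its own
    contig (length preserved) and records the across-region mean of every
    state level.  Returns one row per shuffle.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    regions = _as_regions(regions)
    for row in regions.itertuples():
        size = genome_sizes.get(row.contig)
        if size is None:
            raise ValueError(f"unknown contig in regions: {row.contig}")
        if row.end - row.start > size:
            raise ValueError(
                f"region {row.contig}:{row.start}-{row.end} longer than its contig")
    rng = np.random.default_rng(seed)
    rows = []
    for shuffle_i in range(n_shuffles):
        placed = []
        for row in regions.itertuples():
            length = row.end - row.start
            size = genome_sizes[row.contig]
            start = int(rng.integers(0, size - length + 1))
            placed.append((row.contig, start, start + length))
        means = region_means(fractions, placed)
        rows.append([shuffle_i] + [means[c].mean() for c in VALUE_COLUMNS])
    return pd.DataFrame(rows, columns=["shuffle", *VALUE_COLUMNS])


def binned_profile(fractions: pd.DataFrame, regions, bin_size: int = 200,
                   flank: int = 1000, mode: str = "center",
                   scaled_length: int = 5000) -> pd.DataFrame:
    """Meta-profile of state levels across regions.

    ``center`` mode anchors bins at the region midpoint spanning +/-flank
    real base pairs.  ``scaled`` mode rescales each region body to
    ``scaled_length`` pseudo-bp before binning and adds real-bp flanks.
    Each bin is averaged first within a region, then across regions,
    ignoring bins with no CpG site.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin_size")
    if mode not in ("center", "scaled"):
        raise ValueError("mode must be 'center' or 'scaled'")
    regions = _as_regions(regions)
    n_flank = flank // bin_size
    if mode == "center":
        n_bins = 2 * n_flank
        labels = [(-flank + (i + 0.5) * bin_size) for i in range(n_bins)]
    else:
        n_body = max(1, scaled_length // bin_size)
        n_bins = n_body + 2 * n_flank
        labels = ([-flank + (i + 0.5) * bin_size for i in range(n_flank)]
                  + [(i + 0.5) * bin_size for i in range(n_body)]
                  + [scaled_length + (i + 0.5) * bin_size for i in range(n_flank)])

    by_contig = dict(tuple(fractions.groupby("contig", sort=False)))
    per_region = np.full((len(regions), n_bins, len(VALUE_COLUMNS)), np.nan)
    for r_i, row in enumerate(regions.itertuples()):
        sub = by_contig.get(row.contig)
        if sub is None:
            continue
        pos = sub["pos0"].to_numpy()
        vals = sub[VALUE_COLUMNS].to_numpy()
        if mode == "center":
            mid = (row.start + row.end) // 2
            rel = pos - (mid - flank)
            bins = np.floor_divide(rel, bin_size)
            ok = (rel >= 0) & (bins < n_bins)
        else:
            length = max(1, row.end - row.start)
            bins = np.full(len(pos), -1)
            left = (pos >= row.start - flank) & (pos < row.start)
            bins[left] = (pos[left] - (row.start - flank)) // bin_size
            body = (pos >= row.start) & (pos < row.end)
            scaled = (pos[body] - row.start) / length * (n_bins - 2 * n_flank)
            bins[body] = n_flank + np.minimum(scaled.astype(int),
                                              n_bins - 2 * n_flank - 1)
            right = (pos >= row.end) & (pos < row.end + flank)
            bins[right] = n_bins - n_flank + (pos[right] - row.end) // bin_size
            ok = bins >= 0
        for b in np.unique(bins[ok]):
            sel = ok & (bins == b)
            per_region[r_i, int(b)] = np.nanmean(vals[sel], axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        profile = np.nanmean(per_region, axis=0)
    out = pd.DataFrame(profile, columns=VALUE_COLUMNS)
    out.insert(0, "bin_center", labels)
    return out


def write_frame(df: pd.DataFrame, path, comments: Sequence[str] = ()):
    write_table(df, path, comments)
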