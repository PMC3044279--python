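"""Heterozygous-site tracks: loading real variant lists and synthesizing
tracks with heavy-tailed inter-SNP spacing.

A track is the substrate every simulated experiment runs on: a sorted list
of heterozygous-site coordinates over a region of length ``G``, optionally
carrying the two true haplotype allele vectors for accuracy evaluation.
Coordinates are 0-based and half-open throughout the package; VCF input is
converted on read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "VariantTrack",
    "EmptyTrackError",
    "load_track_from_vcf",
    "load_track_from_positions",
    "synthesize_powerlaw_track",
    "inter_snp_distances",
    "write_track_tsv",
]


class EmptyTrackError(ValueError):
    """Raised when a source yields zero heterozygous sites."""


@dataclass(frozen=True)
class VariantTrack:
    """A sorted list of heterozygous-site positions over ``[0, region_length)``.

    Parameters
    ----------
    positions
        Strictly increasing 0-based site coordinates (bp).
    region_length
        Length ``G`` of the region in bp.
    truth
        Optional pair of haplotype allele vectors over ``{0, 1}``, one entry
        per site; the two vectors must differ at every index (all sites
        heterozygous).
    label
        Free-text provenance.
    """

    positions: np.ndarray
    region_length: int
    truth: Optional[Tuple[np.ndarray, np.ndarray]] = None
    label: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 1:
            raise ValueError("positions must be one-dimensional")
        if pos.size and (np.any(np.diff(pos) <= 0)):
            raise ValueError("positions must be strictly increasing")
        if pos.size and (pos[0] < 0 or pos[-1] >= self.region_length):
            raise ValueError("positions must lie in [0, region_length)")
        if self.truth is not None:
            h1 = np.asarray(self.truth[0], dtype=np.int8)
            h2 = np.asarray(self.truth[1], dtype=np.int8)
            if h1.shape != (pos.size,) or h2.shape != (pos.size,):
                raise ValueError("truth vectors must have one entry per site")
            if np.any(h1 == h2):
                raise ValueError("truth haplotypes must differ at every site")
            object.__setattr__(self, "truth", (h1, h2))

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def __len__(self) -> int:
        return self.n_sites

    def metadata(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "region_length": int(self.region_length),
            "has_truth": self.truth is not None,
            "label": self.label,
        }


def _finalize_positions(
    positions: Sequence[int], region_length: int, label: str, source: str
) -> VariantTrack:
    pos = np.asarray(sorted(positions), dtype=np.int64)
    if pos.size == 0:
        raise EmptyTrackError(f"no heterozygous sites loaded from {source}")
    uniq = np.unique(pos)
    if uniq.size < pos.size:
        logger.info(
            "%s: deduplicated %d repeated positions", source, pos.size - uniq.size
        )
    if uniq[-1] >= region_length:
        raise ValueError(
            f"{source}: position {uniq[-1]} >= region_length {region_length}"
        )
    return VariantTrack(uniq, region_length, label=label)


def load_track_from_vcf(
    path: str | Path,
    region: Optional[Tuple[int, int]] = None,
    chrom: Optional[str] = None,
    sample: int = 0,
) -> VariantTrack:
    """Load biallelic heterozygous SNVs from a VCF into a track.

    Positions are shifted to be region-relative and 0-based. ``region`` is a
    half-open ``[start, end)`` interval in 0-based coordinates on ``chrom``
    (or the file's single chromosome). Multi-allelic records, indels, and
    non-heterozygous genotypes are skipped (counts logged).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    start, end = region if region is not None else (0, None)
    positions = []
    skipped = 0
    for rec in vcf:
        if chrom is not None and rec.CHROM != chrom:
            continue
        pos0 = rec.POS - 1  # VCF is 1-based
        if pos0 < start or (end is not None and pos0 >= end):
            continue
        if len(rec.ALT) != 1 or not rec.is_snp:
            skipped += 1
            continue
        gts = rec.genotypes
        if not gts:
            skipped += 1
            continue
        a, b = gts[sample][0], gts[sample][1]
        if {a, b} != {0, 1}:
            continue  # not a 0/1 heterozygote
        positions.append(pos0 - start)
    if skipped:
        logger.info("%s: skipped %d non-biallelic/non-SNV records", path, skipped)
    region_length = (end - start) if end is not None else (max(positions) + 1 if positions else 0)
    return _finalize_positions(positions, region_length, label=str(path), source=str(path))


def load_track_from_positions(
    path: str | Path, format: str, region_length: int
) -> VariantTrack:
    """Load a track from a BED (width-1 intervals) or one-column TSV file.

    Positions are sorted and deduplicated; a position at or beyond
    ``region_length`` or a malformed line is an error.
    """
    fmt = format.lower()
    if fmt not in {"bed", "tsv"}:
        raise ValueError(f"unknown format {format!r}; expected 'bed' or 'tsv'")
    positions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    start_, end_ = int(fields[1]), int(fields[2])
                    if end_ - start_ != 1:
                        raise ValueError("BED interval is not width 1")
                    positions.append(start_)
                else:
                    positions.append(int(fields[0]))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from exc
    return _finalize_positions(positions, region_length, label=str(path), source=str(path))


def synthesize_powerlaw_track(
    region_length: int,
    mean_gap: float = 1000.0,
    tail_exponent: float = 2.5,
    min_gap: int = 1,
    seed: int = 0,
) -> VariantTrack:
    """Synthesize a het-site track with power-law distributed inter-SNP gaps.

    Human heterozygous sites average roughly one per kbp but cluster: the
    inter-site distance distribution has a much heavier tail than the
    exponential a homogeneous Poisson process would give. Gaps here are
    ``min_gap + floor(X)`` with ``X`` a continuous Pareto variate of the
    given tail exponent, affinely rescaled so the expected gap is
    ``mean_gap``. Truth haplotypes are the fixed complementary pair (all-0 /
    all-1); haplotype accuracy metrics are invariant to allele labels.

    Parameters
    ----------
    region_length
        Region length G in bp.
    mean_gap
        Target expected inter-site distance in bp (default 1000, the
        genome-wide average spacing of heterozygous SNVs in a human).
    tail_exponent
        Pareto tail index (> 1 so the mean exists; default 2.5).
    min_gap
        Smallest possible gap in bp (>= 1).
    seed
        Seed for the gap-sampling random stream.
    """
    if not (mean_gap >= min_gap >= 1):
        raise ValueError("require mean_gap >= min_gap >= 1")
    if tail_exponent <= 1:
        raise ValueError("tail_exponent must exceed 1 for the mean to exist")
    rng = np.random.default_rng(seed)
    a = tail_exponent
    # E[Pareto(a, xm=1)] - 1 = 1/(a-1); scale to hit mean_gap, with +0.5
    # compensating the downward bias of the floor.
    scale = (mean_gap - min_gap + 0.5) * (a - 1.0)
    block = max(64, int(1.3 * region_length / mean_gap) + 64)
    chunks: list[np.ndarray] = []
    total = 0
    while total < region_length:
        gaps = min_gap + np.floor(scale * rng.pareto(a, size=block)).astype(np.int64)
        chunks.append(gaps)
        total += int(gaps.sum())
    cum = np.cumsum(np.concatenate(chunks))
    pos_arr = cum[cum < region_length]
    truth = (
        np.zeros(pos_arr.size, dtype=np.int8),
        np.ones(pos_arr.size, dtype=np.int8),
    )
    return VariantTrack(
        pos_arr,
        region_length,
        truth=truth if pos_arr.size else None,
        label=f"synthetic-powerlaw(mean_gap={mean_gap},a={tail_exponent},seed={seed})",
    )


def inter_snp_distances(track: VariantTrack) -> np.ndarray:
    """Gaps between consecutive sites, in bp. Requires at least 2 sites."""
    if track.n_sites < 2:
        raise ValueError("need at least 2 sites to compute inter-SNP distances")
    return np.diff(track.positions)


def write_track_tsv(track: VariantTrack, path: str | Path) -> None:
    """Write positions one per line; companion .json holds metadata."""
    path = Path(path)
    with open(path, "w") as fh:
        for p in track.positions:
            fh.write(f"{int(p)}\n")
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(track.metadata(), fh, indent=2)
        fh.write("\n")
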