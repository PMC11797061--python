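"""Per-nucleotide SHAPE reactivity from mutation/coverage count tables.

Chemical probing with NAI leaves adducts on conformationally flexible
(mostly unpaired) nucleotides; during reverse transcription the adducts are
read out as mutations.  Reactivity is computed as the per-base mutation-rate
difference between the NAI channel and the DMSO control channel, then scaled
by 1.5 times the interquartile range of the raw reactivities of the RNA.
Positions are only reported where sequencing coverage strictly exceeds a
depth threshold (default 10 000x) in every contributing channel.

Coordinates are 1-based and inclusive throughout; masked (undefined)
positions are carried as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import (
    DegenerateScaleError,
    InsufficientDataError,
    IntegrityError,
)

MASK_SENTINEL = -999.0  # conventional "no data" value of SHAPE constraint files
DEFAULT_COVERAGE_THRESHOLD = 10_000


@dataclass
class MutationCountTable:
    """Counts for one RNA, one channel (NAI or DMSO), one replicate.

    ``coverage`` and ``mutations`` are aligned integer arrays over positions
    1..L; ``mutations`` sums mismatches, insertions and deletions assigned to
    the position (insertions at the 5'-most reference position they follow,
    deletions at their first deleted position).
    """

    rna_id: str
    channel: str  # "NAI" or "DMSO"
    replicate: int
    coverage: np.ndarray
    mutations: np.ndarray
    ref_base: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        self.mutations = np.asarray(self.mutations, dtype=np.int64)
        if self.coverage.shape != self.mutations.shape:
            raise IntegrityError(
                f"{self.rna_id}: coverage and mutation arrays differ in length"
            )
        if np.any(self.coverage < 0) or np.any(self.mutations < 0):
            raise IntegrityError(f"{self.rna_id}: negative counts")
        bad = np.nonzero(self.mutations > self.coverage)[0]
        if bad.size:
            raise IntegrityError(
                f"{self.rna_id} ({self.channel} rep {self.replicate}): "
                f"mutations exceed coverage at position {bad[0] + 1}"
            )

    def __len__(self) -> int:
        return int(self.coverage.size)

    @property
    def positions(self) -> np.ndarray:
        """1-based contiguous position index."""
        return np.arange(1, len(self) + 1)


@dataclass
class ReactivityProfile:
    """Raw and IQR-normalized reactivities for one RNA.

    ``normalized = raw / (1.5 * (Q3 - Q1))`` with quartiles taken over the
    unmasked raw values; ``coverage_ok`` marks positions whose coverage
    strictly exceeded the threshold in every contributing count table.
    ``replicate`` is an integer label or the string ``"mean"``.
    """

    rna_id: str
    raw: np.ndarray
    normalized: np.ndarray
    coverage_ok: np.ndarray
    q1: float
    q3: float
    scale: float
    replicate: int | str = 1

    def __len__(self) -> int:
        return int(self.raw.size)

    @property
    def reported(self) -> np.ndarray:
        """Normalized reactivity with non-reportable positions set to NaN."""
        out = np.array(self.normalized, dtype=float)
        out[~self.coverage_ok] = np.nan
        return out


def mutation_rates(table: MutationCountTable) -> np.ndarray:
    """Per-position mutation rate ``mutations / coverage``.

    Positions with zero coverage are undefined and returned as NaN rather
    than zero.
    """
    cov = table.coverage.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(cov > 0, table.mutations / cov, np.nan)
    return rates


def raw_reactivity(nai_rates: np.ndarray, dmso_rates: np.ndarray) -> np.ndarray:
    """Elementwise NAI minus DMSO mutation rate for one replicate.

    Negative differences are retained (not clipped); NaN in either channel
    propagates.
    """
    nai = np.asarray(nai_rates, dtype=float)
    dmso = np.asarray(dmso_rates, dtype=float)
    if nai.shape != dmso.shape:
        raise IntegrityError("NAI and DMSO rate vectors differ in length")
    return nai - dmso


def coverage_filter(
    tables: Iterable[MutationCountTable],
    threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> np.ndarray:
    """Boolean mask: coverage strictly greater than ``threshold`` everywhere.

    A position passes only if every contributing table (e.g. the NAI and the
    DMSO channel of the replicate at hand) exceeds the threshold.
    """
    if threshold < 0:
        raise ValueError("coverage threshold must be >= 0")
    tables = list(tables)
    if not tables:
        raise InsufficientDataError("no count tables supplied")
    mask = np.ones(len(tables[0]), dtype=bool)
    for t in tables:
        if len(t) != mask.size:
            raise IntegrityError("count tables differ in length")
        mask &= t.coverage > threshold
    return mask


def normalize_iqr(
    raw: np.ndarray,
    mask: np.ndarray | None = None,
    rna_id: str = "",
    replicate: int | str = 1,
    min_positions: int = 8,
) -> ReactivityProfile:
    """IQR-scale a raw reactivity profile.

    Quartiles Q1/Q3 are the 25th/75th percentiles of the unmasked raw values
    (negative values included), computed with linear interpolation between
    closest order statistics; the normalization scale is ``1.5 * (Q3 - Q1)``.

    ``mask`` restricts which positions enter the quartile computation (and
    are flagged ``coverage_ok``); all finite raw values are normalized
    regardless, so that downstream consumers can apply their own reporting
    rule.
    """
    raw = np.asarray(raw, dtype=float)
    if mask is None:
        mask = np.isfinite(raw)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(raw)
    values = raw[mask]
    if values.size < min_positions:
        raise InsufficientDataError(
            f"only {values.size} unmasked positions; need >= {min_positions}"
        )
    q1, q3 = np.percentile(values, [25.0, 75.0], method="linear")
    scale = 1.5 * (q3 - q1)
    if scale <= 0:
        raise DegenerateScaleError(
            f"degenerate raw reactivity spread (Q1 == Q3 == {q1:g})"
        )
    normalized = raw / scale
    return ReactivityProfile(
        rna_id=rna_id,
        raw=raw,
        normalized=normalized,
        coverage_ok=mask,
        q1=float(q1),
        q3=float(q3),
        scale=float(scale),
        replicate=replicate,
    )


def replicate_profile(
    nai: MutationCountTable,
    dmso: MutationCountTable,
    threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    quartiles_after_filter: bool = True,
) -> ReactivityProfile:
    """Full raw->normalized pipeline for one paired NAI/DMSO replicate.

    NAI replicate k is subtracted against DMSO replicate k; each replicate is
    normalized on its own quartiles before any cross-replicate statistics.
    By default quartiles are computed on coverage-filtered positions only
    (``quartiles_after_filter=False`` computes them on all defined positions).
    """
    if nai.rna_id != dmso.rna_id:
        raise IntegrityError(
            f"channel tables belong to different RNAs: {nai.rna_id!r} vs {dmso.rna_id!r}"
        )
    raw = raw_reactivity(mutation_rates(nai), mutation_rates(dmso))
    cov_ok = coverage_filter([nai, dmso], threshold)
    norm_mask = cov_ok if quartiles_after_filter else None
    profile = normalize_iqr(
        raw, mask=norm_mask, rna_id=nai.rna_id, replicate=nai.replicate
    )
    # coverage_ok reflects the depth rule even when quartiles ignored it
    profile.coverage_ok = cov_ok & np.isfinite(raw)
    return profile


def mean_profile(profiles: Sequence[ReactivityProfile]) -> ReactivityProfile:
    """Average normalized reactivity across replicates.

    A position is kept only where every replicate passes the coverage rule
    (conservative masking keeps the per-position replicate count, and hence
    the variance of the mean, constant).  Negative means are retained in the
    data; plotting layers are expected to drop them.
    """
    if not profiles:
        raise InsufficientDataError("no replicate profiles supplied")
    length = len(profiles[0])
    if any(len(p) != length for p in profiles):
        raise IntegrityError("replicate profiles differ in length")
    stack = np.vstack([p.normalized for p in profiles])
    ok = np.all(
        np.vstack([p.coverage_ok for p in profiles]), axis=0
    ) & np.all(np.isfinite(stack), axis=0)
    mean = np.full(length, np.nan)
    mean[ok] = stack[:, ok].mean(axis=0)
    return ReactivityProfile(
        rna_id=profiles[0].rna_id,
        raw=np.full(length, np.nan),
        normalized=mean,
        coverage_ok=ok,
        q1=float("nan"),
        q3=float("nan"),
        scale=float("nan"),
        replicate="mean",
    )


def export_shape(profile: ReactivityProfile, path) -> None:
    """Write a SHAPE constraint file: ``index reactivity`` per line.

    Positions that fail the coverage rule (or are undefined) are written as
    -999, the conventional no-data sentinel of SHAPE-directed folding tools.
    """
    if len(profile) == 0:
        raise InsufficientDataError("cannot export an empty profile")
    values = profile.reported
    with open(path, "w") as fh:
        for i, v in enumerate(values, start=1):
            if np.isfinite(v):
                fh.write(f"{i} {v:.4f}\n")
            else:
                fh.write(f"{i} {MASK_SENTINEL:.0f}\n")


def read_shape(path) -> np.ndarray:
    """Read a SHAPE constraint file back to a NaN-masked reactivity vector."""
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            idx_s, val_s = line.split()
            idx, val = int(idx_s), float(val_s)
            if idx != len(values) + 1:
                raise IntegrityError(f"non-contiguous position {idx} in {path}")
            values.append(np.nan if val == MASK_SENTINEL else val)
    if not values:
        raise InsufficientDataError(f"empty constraint file: {path}")
    return np.array(values)
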