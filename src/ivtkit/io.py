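"""File readers and writers for the toolkit's text formats.

Conventions: 1-based inclusive coordinates in all count tables and
constraint files; reals serialized with 6 significant digits so that
identical runs produce byte-identical files; undefined values written as
``nan``.  All tabular formats are plain TSV/CSV with headers; images are
single-channel TIFF or PNG.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO

from .dose_response import DoseResponseDataset
from .exceptions import FormatError, IntegrityError
from .shape import MutationCountTable, ReactivityProfile
from .titer import DilutionAssay

FLOAT_FMT = "%.6g"

COUNTS_COLUMNS = [
    "rna_id", "position", "ref_base", "channel", "replicate",
    "coverage", "mutations",
]
PLATE_COLUMNS = [
    "group", "concentration_ng_ml", "od", "replicate",
    "dilution_factor", "is_blank", "is_standard", "standard_conc",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path, rna_mode: bool = True) -> dict[str, str]:
    """Read FASTA records as {id: uppercase sequence} (T -> U in RNA mode)."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if rna_mode:
            seq = seq.replace("T", "U")
        records[rec.id] = seq
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


# ---------------------------------------------------------------------------
# mutation count tables
# ---------------------------------------------------------------------------


def read_counts(path) -> list[MutationCountTable]:
    """Read a counts TSV into validated tables, one per
    (rna_id, channel, replicate); table invariants are enforced at load."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns and c != "ref_base"]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    tables = []
    for (rna_id, channel, replicate), sub in df.groupby(
        ["rna_id", "channel", "replicate"], sort=True
    ):
        sub = sub.sort_values("position")
        positions = sub["position"].to_numpy()
        if not np.array_equal(positions, np.arange(1, positions.size + 1)):
            raise FormatError(
                f"{path}: positions for {rna_id}/{channel}/rep{replicate} "
                "are not contiguous from 1"
            )
        tables.append(
            MutationCountTable(
                rna_id=str(rna_id),
                channel=str(channel),
                replicate=int(replicate),
                coverage=sub["coverage"].to_numpy(),
                mutations=sub["mutations"].to_numpy(),
                ref_base=(
                    sub["ref_base"].tolist() if "ref_base" in sub.columns else None
                ),
            )
        )
    if not tables:
        raise FormatError(f"{path}: empty counts table")
    return tables


def write_counts(tables: list[MutationCountTable], path) -> None:
    rows = []
    for t in tables:
        refs = t.ref_base if t.ref_base is not None else ["N"] * len(t)
        for i in range(len(t)):
            rows.append(
                (t.rna_id, i + 1, refs[i], t.channel, t.replicate,
                 int(t.coverage[i]), int(t.mutations[i]))
            )
    pd.DataFrame(rows, columns=COUNTS_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reactivity profiles / replicate matrices
# ---------------------------------------------------------------------------


def write_profile(profile: ReactivityProfile, path) -> None:
    df = pd.DataFrame(
        {
            "position": np.arange(1, len(profile) + 1),
            "raw": profile.raw,
            "normalized": profile.normalized,
            "coverage_ok": profile.coverage_ok.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_profile(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("position", "normalized", "coverage_ok"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return df


def write_replicate_matrix(profiles, path) -> None:
    """Write replicate-column reactivity TSV (position, rep_<k>...).

    Positions failing a replicate's coverage rule are written as nan for
    that replicate.
    """
    data = {"position": np.arange(1, len(profiles[0]) + 1)}
    for p in profiles:
        data[f"rep_{p.replicate}"] = p.reported
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_replicate_matrix(path) -> np.ndarray:
    """Read a replicate-column reactivity TSV into positions x replicates."""
    df = pd.read_csv(path, sep="\t")
    rep_cols = [c for c in df.columns if c.startswith("rep_")]
    if not rep_cols:
        raise FormatError(f"{path}: no replicate columns (rep_*)")
    return df[rep_cols].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# dose-response plates
# ---------------------------------------------------------------------------


def read_plate(path) -> dict[str, DoseResponseDataset]:
    """Read a plate CSV into one blank-aware dataset per group.

    Blank wells (is_blank = 1) contribute their OD to the group's blank set;
    standard wells (is_standard = 1) are returned under the reserved group
    name of the standard rather than as fit points.
    """
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    datasets: dict[str, DoseResponseDataset] = {}
    for group, sub in df.groupby("group", sort=True):
        blanks = sub.loc[sub["is_blank"] == 1, "od"].to_numpy(dtype=float)
        pts = sub[(sub["is_blank"] != 1)]
        if (pts["is_standard"] == 1).any():
            conc = pts["standard_conc"].to_numpy(dtype=float)
        else:
            conc = pts["concentration_ng_ml"].to_numpy(dtype=float)
        dilution = pts["dilution_factor"].to_numpy(dtype=float)
        datasets[str(group)] = DoseResponseDataset(
            group=str(group),
            concentration=conc,
            od=pts["od"].to_numpy(dtype=float),
            replicate=pts["replicate"].to_numpy(),
            blanks=blanks,
            dilution_factor=float(dilution[0]) if dilution.size else 1.0,
        )
    return datasets


def write_plate(rows: pd.DataFrame, path) -> None:
    missing = [c for c in PLATE_COLUMNS if c not in rows.columns]
    if missing:
        raise FormatError(f"plate frame missing column(s) {', '.join(missing)}")
    rows.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# titration / blot tables
# ---------------------------------------------------------------------------


def read_titer_table(path) -> DilutionAssay:
    df = pd.read_csv(path, sep="\t")
    for col in ("exponent", "wells_total", "wells_infected"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    df = df.sort_values("exponent")
    return DilutionAssay(
        exponents=df["exponent"].to_numpy(dtype=float),
        wells_total=df["wells_total"].to_numpy(),
        wells_infected=df["wells_infected"].to_numpy(),
    )


def write_titer_table(assay: DilutionAssay, path) -> None:
    pd.DataFrame(
        {
            "exponent": assay.exponents,
            "wells_total": assay.wells_total,
            "wells_infected": assay.wells_infected,
        }
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_blot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "group", "amount_or_unknown", "intensity"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# JSON reports and images
# ---------------------------------------------------------------------------


def _round_floats(obj, sig: int = 6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        if not math.isfinite(x):
            return None
        return float(f"{x:.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(data: dict, path) -> None:
    """JSON report with floats fixed at 6 significant digits (deterministic)."""
    with open(path, "w") as fh:
        json.dump(_round_floats(data), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(str(path))
    else:
        img = iio.imread(str(path))
    img = np.asarray(img)
    if img.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel image")
    return img.astype(float)


def write_image(image: np.ndarray, path) -> None:
    path = Path(path)
    arr = np.asarray(image)
    clipped = np.clip(np.rint(arr), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), clipped)
    else:
        iio.imwrite(str(path), clipped)
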