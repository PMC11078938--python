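"""Readers and writers: stack manifests, TIFF images, CSV tables, FASTA.

A *stack manifest* is a CSV with columns ``cycle, channel, role, path``
(role in {reference, stained, erased, spot}) describing where each image of
an experiment lives.  Images are normalised to [0, 1] at load time by the
recorded dtype range, so intensity thresholds have one meaning everywhere.

CSV dialect throughout: comma-separated, dot decimal, UTF-8, header row,
no index column.  All writers are deterministic (no timestamps), so a run
directory is byte-reproducible from (inputs, config, seed).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO

from .stack import Cycle, CycleStack, MarkerChannel
from .synth import GroundTruth

__all__ = [
    "read_image",
    "write_image",
    "read_manifest",
    "read_stack",
    "write_stack",
    "write_ground_truth",
    "read_transcripts_fasta",
    "write_probes_fasta",
]

log = logging.getLogger(__name__)

ROLES = {"reference", "stained", "erased", "spot"}


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image and normalise to [0, 1] by its dtype range."""
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single 2-D page, got shape {img.shape}")
    dtype = img.dtype
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        out = img.astype(float) / info.max
    else:
        out = img.astype(float)
    log.debug("read %s dtype=%s range=[%.4g, %.4g]", path, dtype, out.min(), out.max())
    return out


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a float image as float32 TIFF (no timestamp metadata)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_manifest(path: str | Path) -> pd.DataFrame:
    man = pd.read_csv(path)
    required = {"cycle", "channel", "role", "path"}
    missing = required - set(man.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad = set(man["role"]) - ROLES
    if bad:
        raise ValueError(f"manifest has unknown roles: {sorted(bad)}")
    return man


def read_stack(manifest: str | Path | pd.DataFrame) -> CycleStack:
    """Load a CycleStack from a manifest (path or pre-read DataFrame).

    Validates: exactly one reference per cycle, stained/erased images paired
    per (cycle, channel), consistent dimensions.  Relative paths resolve
    against the manifest's directory.
    """
    if isinstance(manifest, (str, Path)):
        base = Path(manifest).parent
        man = read_manifest(manifest)
    else:
        base = Path(".")
        man = manifest
    cycles: list[Cycle] = []
    for cyc_idx in sorted(man["cycle"].unique()):
        rows = man[man["cycle"] == cyc_idx]
        refs = rows[rows["role"] == "reference"]
        if len(refs) != 1:
            raise ValueError(f"cycle {cyc_idx}: need exactly 1 reference, got {len(refs)}")
        reference = read_image(base / refs.iloc[0]["path"])
        channels = []
        marker_rows = rows[rows["role"].isin(["stained", "erased"])]
        for name in sorted(marker_rows["channel"].unique()):
            sub = marker_rows[marker_rows["channel"] == name]
            stained = sub[sub["role"] == "stained"]
            erased = sub[sub["role"] == "erased"]
            if len(stained) != 1:
                raise ValueError(
                    f"cycle {cyc_idx} channel {name}: need exactly 1 stained image"
                )
            channels.append(
                MarkerChannel(
                    name=str(name),
                    stained=read_image(base / stained.iloc[0]["path"]),
                    erased=(read_image(base / erased.iloc[0]["path"])
                            if len(erased) == 1 else None),
                )
            )
        cycles.append(Cycle(int(cyc_idx), reference, channels))
    return CycleStack(cycles)


def write_stack(stack: CycleStack, outdir: str | Path) -> Path:
    """Write every image of a stack as TIFF plus a manifest.csv; returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cyc in stack.cycles:
        ref_path = f"cycle{cyc.index:02d}_reference.tif"
        write_image(cyc.reference, outdir / ref_path)
        rows.append((cyc.index, "DNA", "reference", ref_path))
        for ch in cyc.channels:
            sp = f"cycle{cyc.index:02d}_{ch.name}_stained.tif"
            write_image(ch.stained, outdir / sp)
            rows.append((cyc.index, ch.name, "stained", sp))
            if ch.erased is not None:
                ep = f"cycle{cyc.index:02d}_{ch.name}_erased.tif"
                write_image(ch.erased, outdir / ep)
                rows.append((cyc.index, ch.name, "erased", ep))
    man = pd.DataFrame(rows, columns=["cycle", "channel", "role", "path"])
    man_path = outdir / "manifest.csv"
    man.to_csv(man_path, index=False)
    return man_path


def write_ground_truth(truth: GroundTruth, outdir: str | Path) -> None:
    """Ground truth as one label-mask TIFF plus CSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "true_labels.tif", truth.label_image.astype(np.int32))
    truth.ellipses.to_csv(outdir / "true_ellipses.csv", index=False)
    truth.true_intensity.to_csv(outdir / "true_intensity.csv")
    pd.DataFrame(truth.true_shift, columns=["dy", "dx"]).to_csv(
        outdir / "true_shifts.csv", index_label="cycle"
    )
    truth.true_spots.to_csv(outdir / "true_spots.csv", index=False)


def read_transcripts_fasta(path: str | Path, gene_delimiter: str = "|") -> dict[str, dict[str, str]]:
    """Parse a transcript FASTA into gene -> {transcript_id: sequence}.

    The record id is ``gene<delim>transcript`` (or just a gene id, in which
    case the record id doubles as the transcript id).
    """
    records: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if gene_delimiter in rec.id:
            gene, tx = rec.id.split(gene_delimiter, 1)
        else:
            gene, tx = rec.id, rec.id
        records.setdefault(gene, {})[tx] = str(rec.seq).upper()
    return records


def write_probes_fasta(probes, path: str | Path) -> None:
    """Write primary probes as FASTA (`>gene|position`)."""
    with open(path, "w") as fh:
        for p in probes.all_probes():
            fh.write(f">{p.gene}|{p.position}\n{p.sequence}\n")
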