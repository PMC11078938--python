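"""End-to-end runs: synthetic experiment -> aligned, quantified outputs.

``run_all`` executes simulate -> align -> segment -> quantify -> spots ->
spatial on one seed and writes every artefact (TIFFs, CSVs, a
machine-readable JSON run log).  All outputs are pure functions of
(config, seed), and no writer records a timestamp, so repeat runs produce
byte-identical directories.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import RunConfig, save_config
from .detect import detect_spots
from .io import write_ground_truth, write_stack
from .quantify import run_seqis_pipeline, spot_metrics
from .spatial import build_weights, grid_smooth, spatial_corr
from .synth import make_experiment, make_spot_images

__all__ = ["run_all", "CYTOSOL_LABEL_OFFSET"]

log = logging.getLogger(__name__)

#: cytosol ids in the combined region label TIFF are cell_id + this offset
CYTOSOL_LABEL_OFFSET = 100_000


def run_all(config: RunConfig, outdir: str | Path, dry_run: bool = False) -> Path:
    """Run the full synthetic pipeline into ``outdir``; returns the path.

    With ``dry_run=True`` only the configuration is validated and echoed;
    no images are generated or touched.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(config, outdir / "config.yaml")
    if dry_run:
        log.info("dry run: config validated, nothing executed")
        return outdir

    warnings: list[str] = []

    # simulate
    stack, truth = make_experiment(config.synth)
    write_stack(stack, outdir / "images")
    write_ground_truth(truth, outdir / "truth")

    # align + segment + quantify
    table, regions, record = run_seqis_pipeline(
        stack,
        nucleus_params=config.nucleus,
        max_shift=config.max_shift,
        expand=config.cytosol_expand,
    )
    warnings.extend(record.warnings)
    pd.DataFrame(
        [(i, s.dy, s.dx, s.similarity) for i, s in enumerate(record.shifts)],
        columns=["cycle", "dy", "dx", "similarity"],
    ).to_csv(outdir / "shifts.csv", index=False)
    combined = regions.nucleus_labels.astype(np.int32).copy()
    cyt = regions.cytosol_labels
    combined[cyt > 0] = cyt[cyt > 0] + CYTOSOL_LABEL_OFFSET
    tifffile.imwrite(outdir / "region_labels.tif", combined)
    table.to_csv(outdir / "features.csv")

    regions_rows = []
    for cid, e in zip(regions.cell_ids, regions.ellipses):
        regions_rows.append(
            {
                "cell_id": cid,
                "centroid_row": e.centroid[0],
                "centroid_col": e.centroid[1],
                "semi_major": e.semi_major,
                "semi_minor": e.semi_minor,
                "orientation": e.orientation,
                "nucleus_area": int((regions.nucleus_labels == cid).sum()),
                "cytosol_area": int((regions.cytosol_labels == cid).sum()),
            }
        )
    pd.DataFrame(regions_rows).to_csv(outdir / "regions.csv", index=False)

    # spots
    spot_images = make_spot_images(config.synth, truth)
    spot_rows = []
    spot_counts = {}
    unassigned = {}
    for gene, img in spot_images.items():
        spots = detect_spots(img, config.spots)
        spots.insert(0, "gene", gene)
        spot_rows.append(spots)
        counts, miss = spot_metrics(spots, regions)
        spot_counts[gene] = counts
        unassigned[gene] = miss
    all_spots = pd.concat(spot_rows, ignore_index=True) if spot_rows else pd.DataFrame()
    all_spots.to_csv(outdir / "spots.csv", index=False)
    count_table = pd.concat(
        {g: c for g, c in spot_counts.items()}, axis=1
    ) if spot_counts else pd.DataFrame()
    if not count_table.empty:
        count_table.columns = [f"{g}__{comp}" for g, comp in count_table.columns]
    count_table.to_csv(outdir / "spot_counts.csv")

    # spatial statistics on the nucleus means
    marker_cols = [c for c in table.columns if c.endswith("__nucleus")]
    if regions.n_cells >= 2 and marker_cols:
        coords = table[["centroid_row", "centroid_col"]].to_numpy()
        # v_i for the spatial statistic: plain per-protein z-scores
        sub = table[marker_cols]
        zscored = (sub - sub.mean()) / sub.std(ddof=0).replace(0.0, 1.0)
        weights = build_weights(coords)
        corr = spatial_corr(zscored, weights)
        corr.to_csv(outdir / "spatial_correlation.csv")
        grids = {}
        for col in marker_cols:
            gf = grid_smooth(
                table[col].to_numpy(), coords,
                grid_n=config.grid_n, kernel=config.grid_kernel,
                passes=config.grid_passes,
            )
            grids[col] = gf
            pd.DataFrame(gf.smoothed).to_csv(
                outdir / f"grid_{col.replace('__nucleus', '')}.csv", index=False
            )

    run_log = {
        "cycliq_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "shifts": [(s.dy, s.dx) for s in record.shifts],
        "true_shifts": [list(s) for s in truth.true_shift],
        "n_cells_detected": regions.n_cells,
        "n_cells_true": int(config.synth.n_cells),
        "channel_nucleus_means": record.channel_means,
        "spots_unassigned": unassigned,
        "warnings": warnings,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")
    return outdir


def _jsonify(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
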