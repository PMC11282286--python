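"""File I/O: multi-page TIFF videos, CSV traces/tables, JSON configs.

Videos and component images are plain uncompressed multi-page TIFF (one
page per frame/component); traces and correlation tables are CSV; configs,
reports and manifests are JSON. A results bundle carries a manifest with
SHA-256 content hashes so that bit-identical reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .camera import SourceSet, VideoStack
from .demix import DemixResult

__all__ = [
    "read_video_tiff",
    "write_video_tiff",
    "write_truth_bundle",
    "write_results_bundle",
    "read_results_bundle",
]


def read_video_tiff(path) -> VideoStack:
    """Load a multi-page TIFF video (unsigned 8- or 16-bit, one page/frame).

    Pixel values are taken verbatim; the bit depth is inferred from the
    dtype. Mixed dtypes or frame shapes raise with the offending page named.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pages = tf.pages
        n = len(pages)
        if n == 0:
            raise ValueError(f"{path}: empty TIFF")
        first = pages[0].asarray()
        frames = np.empty((n, *first.shape), dtype=first.dtype)
        frames[0] = first
        for i in range(1, n):
            arr = pages[i].asarray()
            if arr.dtype != first.dtype:
                raise ValueError(
                    f"{path}: page {i} dtype {arr.dtype} differs from page 0 ({first.dtype})"
                )
            if arr.shape != first.shape:
                raise ValueError(
                    f"{path}: page {i} shape {arr.shape} differs from page 0 ({first.shape})"
                )
            frames[i] = arr
    if frames.dtype == np.uint8:
        bit_depth = 8
    elif frames.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"{path}: unsupported dtype {frames.dtype}; expected uint8/uint16")
    return VideoStack(frames=frames, bit_depth=bit_depth)


def write_video_tiff(path, video: VideoStack | np.ndarray) -> Path:
    """Write frames as an uncompressed multi-page TIFF."""
    path = Path(path)
    frames = video.frames if isinstance(video, VideoStack) else np.asarray(video)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, frames, photometric="minisblack")
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_truth_bundle(out_dir, video: VideoStack, sources: SourceSet, config: dict) -> dict:
    """Write a simulated experiment: video + ground-truth sidecar files.

    Layout: ``video.tiff`` (camera counts), ``gt_fingerprints.tiff``
    (float32, one page per source), ``gt_traces.csv`` (frame, source_1..N),
    ``config.json`` (positions, roles, generator parameters, hashes).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_video_tiff(out / "video.tiff", video)
    tifffile.imwrite(
        out / "gt_fingerprints.tiff",
        sources.fingerprint_stack().astype(np.float32),
        photometric="minisblack",
    )
    H = sources.trace_matrix()
    df = pd.DataFrame(
        H.T, columns=[f"source_{i + 1}" for i in range(sources.n_sources)]
    )
    df.insert(0, "frame", np.arange(sources.n_frames))
    df.to_csv(out / "gt_traces.csv", index=False)
    record = dict(config)
    record["files"] = {
        name: _sha256(out / name)
        for name in ("video.tiff", "gt_fingerprints.tiff", "gt_traces.csv")
    }
    (out / "config.json").write_text(json.dumps(record, indent=2, default=_json_default))
    return record


def write_results_bundle(
    result: DemixResult,
    out_dir,
    report: Any | None = None,
    config: dict | None = None,
) -> dict:
    """Write a demixing result (and optional evaluation report) atomically.

    Components go to ``components.tiff`` (float32), traces to
    ``nmf_traces.csv``, loss history and solver config to ``fit.json``;
    evaluation tables (ν, γ, AE) and summaries are CSV/JSON when a report is
    given. The manifest (with SHA-256 hashes) is written last, so a partial
    write leaves no manifest behind.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    comps = result.spatial_components
    if comps.ndim == 2:  # (rank, pixels) from a raw-matrix fit
        comps = comps[:, :, None]
    tifffile.imwrite(out / "components.tiff", comps.astype(np.float32), photometric="minisblack")
    written.append("components.tiff")

    H = result.temporal_components
    df = pd.DataFrame(H.T, columns=[f"component_{k + 1}" for k in range(result.rank)])
    df.insert(0, "frame", np.arange(H.shape[1]))
    df.to_csv(out / "nmf_traces.csv", index=False)
    written.append("nmf_traces.csv")

    fit = {
        "rank": result.rank,
        "converged": result.converged,
        "n_iterations": int(result.loss_history.size),
        "final_loss": float(result.loss_history[-1]) if result.loss_history.size else None,
        "loss_history": result.loss_history.tolist(),
        "config": None if result.config is None else vars(result.config) | {},
        "run_config": config,
    }
    (out / "fit.json").write_text(json.dumps(fit, indent=2, default=_json_default))
    written.append("fit.json")

    if report is not None:
        pd.DataFrame(
            report.gt_nmf.values, index=report.gt_nmf.row_labels, columns=report.gt_nmf.col_labels
        ).to_csv(out / "gt_nmf_correlations.csv")
        pd.DataFrame(
            report.gt_gt.values, index=report.gt_gt.row_labels, columns=report.gt_gt.col_labels
        ).to_csv(out / "gt_gt_correlations.csv")
        written += ["gt_nmf_correlations.csv", "gt_gt_correlations.csv"]
        summary = {
            "assignment": {int(k): int(v) for k, v in report.assignment.items()},
            "sorted_sources": [int(i) for i in report.sorted_sources],
            "delta_avg": report.diagonal.delta_avg,
            "sigma_delta": report.diagonal.sigma_delta,
            "subset": [int(i) for i in report.diagonal.subset],
            "fingerprint_correlations": report.fingerprint_correlations.tolist(),
            "n_sources": report.n_sources,
        }
        if report.crosstalk is not None:
            pd.DataFrame(report.crosstalk.ae_matrix).to_csv(out / "ae_matrix.csv")
            written.append("ae_matrix.csv")
            summary["zeta_avg"] = report.crosstalk.zeta_avg
            summary["sigma_zeta"] = report.crosstalk.sigma_zeta
        (out / "report.json").write_text(json.dumps(summary, indent=2, default=_json_default))
        written.append("report.json")

    manifest = {"files": {name: _sha256(out / name) for name in written}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_results_bundle(out_dir) -> dict:
    """Reload a results bundle into arrays/records (inverse of the writer)."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    bundle: dict[str, Any] = {"manifest": manifest}
    bundle["components"] = tifffile.imread(out / "components.tiff")
    traces = pd.read_csv(out / "nmf_traces.csv")
    bundle["temporal_components"] = traces.drop(columns="frame").to_numpy().T
    bundle["fit"] = json.loads((out / "fit.json").read_text())
    if (out / "report.json").exists():
        bundle["report"] = json.loads((out / "report.json").read_text())
    return bundle
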