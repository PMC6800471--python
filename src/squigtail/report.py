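"""Batch processing, tabular output, summaries and per-read diagnostics.

The batch runner walks a directory of FAST5 files, estimates a tail per
read (including a row with a failure reason for every read that could not
be processed) and writes one CSV row per read. Summaries report per-group
count, mean, median, distribution mode (kernel-density argmax) and the
coefficient of variation, the per-group precision metric used for
spike-in experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import PrimerConfig
from .defaults import default_primer_config
from .dna import DnaConfig, estimate_dna_tail
from .fast5 import ExperimentType, ReadFailure, ReadRecord, read_fast5
from .result import TailEstimate
from .rna import RnaConfig, estimate_rna_tail

log = logging.getLogger(__name__)

__all__ = ["run_batch", "estimate_records", "summarize", "plot_read", "CSV_COLUMNS"]

CSV_COLUMNS = [
    "read_id",
    "file_path",
    "read_type",
    "found",
    "failure_reason",
    "tail_start",
    "tail_end",
    "samples_per_nt",
    "tail_length_nt",
    "basecall_model",
]


def estimate_records(
    records: Iterable[ReadRecord],
    mode: str,
    rna_config: RnaConfig | None = None,
    dna_config: DnaConfig | None = None,
    primers: PrimerConfig | None = None,
) -> list[TailEstimate]:
    """Run the appropriate estimator over in-memory reads."""
    mode = ExperimentType(mode)
    primers = primers or default_primer_config()
    out = []
    for rec in records:
        if mode is ExperimentType.RNA:
            out.append(estimate_rna_tail(rec, rna_config))
        else:
            out.append(estimate_dna_tail(rec, dna_config, primers))
    return out


def _process_file(args) -> list[dict]:
    path, mode, rna_config, dna_config, primers, cap = args
    failures: list[ReadFailure] = []
    try:
        records = read_fast5(path, experiment_type=mode, failures=failures)
    except OSError as exc:
        log.error("cannot read %s: %s", path, exc)
        return [
            {
                "read_id": "",
                "file_path": str(path),
                "read_type": "invalid",
                "found": False,
                "failure_reason": "file_error",
                "tail_start": None,
                "tail_end": None,
                "samples_per_nt": None,
                "tail_length_nt": None,
                "basecall_model": "",
            }
        ]
    rows = [
        e.as_row() for e in estimate_records(records, mode, rna_config, dna_config, primers)
    ]
    rows += [
        {
            "read_id": f.read_id,
            "file_path": f.source_path,
            "read_type": "invalid",
            "found": False,
            "failure_reason": f.reason,
            "tail_start": None,
            "tail_end": None,
            "samples_per_nt": None,
            "tail_length_nt": None,
            "basecall_model": "",
        }
        for f in failures
    ]
    if cap is not None:
        for r in rows:
            if r["tail_length_nt"] is not None:
                r["tail_length_nt"] = min(r["tail_length_nt"], cap)
    return rows


def run_batch(
    input_dir: str | Path,
    mode: str,
    output_csv: str | Path | None = None,
    rna_config: RnaConfig | None = None,
    dna_config: DnaConfig | None = None,
    primers: PrimerConfig | None = None,
    workers: int = 1,
    cap: float | None = None,
) -> pd.DataFrame:
    """Estimate tails for every FAST5 file in a directory.

    Rows are sorted by (file, read id) so the output is byte-identical
    regardless of worker count; per-file errors are logged and recorded as
    rows, and the batch continues.
    """
    input_dir = Path(input_dir)
    paths = sorted(input_dir.glob("*.fast5"))
    if not paths:
        raise FileNotFoundError(f"no FAST5 files in {input_dir}")
    jobs = [(p, mode, rna_config, dna_config, primers, cap) for p in paths]
    if workers > 1:
        from multiprocessing import get_context

        with get_context("spawn").Pool(workers) as pool:
            chunks = pool.map(_process_file, jobs)
    else:
        chunks = [_process_file(j) for j in jobs]
    rows = [r for chunk in chunks for r in chunk]
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df = df.sort_values(["file_path", "read_id"], kind="mergesort").reset_index(drop=True)
    n_found = int(df["found"].sum())
    reasons = df.loc[~df["found"], "failure_reason"].value_counts().to_dict()
    log.info("processed %d reads: %d found, failures %s", len(df), n_found, reasons)
    if output_csv is not None:
        df.to_csv(output_csv, index=False, na_rep="NA")
    return df


def density_mode(values: np.ndarray, bw_method: str | float = "silverman") -> float:
    """Distribution mode as the argmax of a Gaussian KDE (Silverman bandwidth)."""
    from scipy.stats import gaussian_kde

    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan")
    if v.size < 3 or np.ptp(v) == 0:
        return float(np.median(v))
    kde = gaussian_kde(v, bw_method=bw_method)
    grid = np.linspace(v.min(), v.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def summarize(
    estimates: pd.DataFrame | Sequence[TailEstimate],
    group_by: str | None = None,
    bw_method: str | float = "silverman",
) -> pd.DataFrame:
    """Per-group summary of found reads: n, mean, median, mode, sd, CV (%)."""
    if not isinstance(estimates, pd.DataFrame):
        estimates = pd.DataFrame([e.as_row() for e in estimates])
    df = estimates[estimates["found"].astype(bool)].copy()
    if group_by is None:
        df["_group"] = "all"
        group_by = "_group"
    rows = []
    for key, sub in df.groupby(group_by, sort=True):
        v = sub["tail_length_nt"].to_numpy(dtype=float)
        if v.size == 0:
            log.warning("group %s has no found reads; omitted", key)
            continue
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        rows.append(
            {
                "group": key,
                "n": int(v.size),
                "mean": mean,
                "median": float(np.median(v)),
                "mode": density_mode(v, bw_method),
                "sd": sd,
                "cv_percent": 100.0 * sd / mean if mean else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def plot_read(
    record: ReadRecord,
    estimate: TailEstimate,
    out_path: str | Path,
    rna_config: RnaConfig | None = None,
) -> Path:
    """Per-read diagnostic figure: raw and normalised signal, smoothed and
    slope tracks, with the called tail region shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .rna import bidirectional_smooth, znormalize_clip

    cfg = rna_config or RnaConfig()
    fig, axes = plt.subplots(3, 1, figsize=(10, 7), sharex=True)
    raw = np.asarray(record.raw_signal, dtype=float)
    axes[0].plot(raw, lw=0.3, color="0.3")
    axes[0].set_ylabel("raw (DAC)")
    z = znormalize_clip(raw, cfg.znorm_clip)
    axes[1].plot(z, lw=0.3, color="0.3")
    axes[1].set_ylabel("z (clipped)")
    if raw.size >= cfg.smooth_window:
        sm = bidirectional_smooth(z, cfg.smooth_window)
        axes[2].plot(sm, lw=0.6, color="tab:blue")
        axes[2].axhline(cfg.segment_threshold, color="tab:red", ls="--", lw=0.8)
    axes[2].set_ylabel("smoothed")
    axes[2].set_xlabel("sample")
    if estimate.found:
        for ax in axes:
            ax.axvspan(estimate.tail_start, estimate.tail_end, color="gold", alpha=0.3)
        title = f"{record.read_id}: {estimate.read_type} tail {estimate.tail_length_nt:.1f} nt"
    else:
        title = f"{record.read_id}: no tail ({estimate.failure_reason})"
    fig.suptitle(title)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=100, metadata={"Software": None})
    plt.close(fig)
    return out_path
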