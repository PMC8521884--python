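"""Readers and writers: OpenFace-dialect CSV, audio, tidy tables, results.

The OpenFace dialect pads header names with spaces (`` AU01_r``); both padded
and plain headers parse identically.  Audio is accepted as 16-bit PCM mono
WAV or as one-column numeric text with a caller-stated sample rate, so the
pipeline needs no codec dependencies.
"""

from __future__ import annotations

import os
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .catalog import MARKER_CATALOG, STIMULUS_CLASSES
from .longitudinal import AnovaResult

OPENFACE_MANDATORY = ("frame", "timestamp", "confidence", "success")

MARKER_TABLE_COLUMNS = ("subject_id", "study_day", "stimulus_class", "marker", "value")

RESULTS_COLUMNS = (
    "condition", "marker", "n", "sphericity", "statistic_kind", "statistic",
    "df_num", "df_den", "p_raw", "p_fdr", "direction",
    "mauchly_w", "mauchly_p", "f_stat", "f_p", "gg_eps", "gg_p",
)


def read_openface_csv(path: str | os.PathLike) -> pd.DataFrame:
    """Parse a per-frame face-tracking CSV in the OpenFace dialect.

    Accepts comma or comma-space delimited headers, preserves unknown columns,
    and raises ``ValueError`` naming any missing mandatory column
    (frame/timestamp/confidence/success plus at least one AU column).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, skipinitialspace=True)
    except pd.errors.ParserError as exc:
        raise ValueError(f"unparseable rows in {path}: {exc}") from exc
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in OPENFACE_MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"{path} lacks mandatory columns: {missing}")
    au_cols = [c for c in df.columns if c.startswith("AU") and c[-2:] in ("_r", "_c")]
    if not au_cols:
        raise ValueError(f"{path} has no AU presence/intensity columns")
    return df


def write_openface_csv(frames: pd.DataFrame, path: str | os.PathLike) -> None:
    frames.to_csv(path, index=False)


def write_wav(samples: np.ndarray, sample_rate: int, path: str | os.PathLike) -> None:
    """Write a mono amplitude trace as 16-bit PCM WAV (clipped to [-1, 1])."""
    x = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0)
    wavfile.write(str(path), int(sample_rate), (x * 32767).astype(np.int16))


def read_wav(path: str | os.PathLike) -> tuple[np.ndarray, int]:
    """Read a mono PCM WAV as floats in [-1, 1] plus its sample rate."""
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        return data.astype(float) / scale, int(rate)
    return data.astype(float), int(rate)


def write_text_audio(samples: np.ndarray, path: str | os.PathLike) -> None:
    np.savetxt(str(path), np.asarray(samples, dtype=float), fmt="%.9g")


def read_text_audio(path: str | os.PathLike, sample_rate: int) -> tuple[np.ndarray, int]:
    if sample_rate <= 0:
        raise ValueError("a positive sample rate must be stated for text audio")
    return np.loadtxt(str(path), dtype=float), int(sample_rate)


def read_audio(path: str | os.PathLike, sample_rate: int | None = None) -> tuple[np.ndarray, int]:
    """Dispatch on extension: ``.wav`` or numeric text (rate required)."""
    p = Path(path)
    if p.suffix.lower() == ".wav":
        return read_wav(p)
    if sample_rate is None:
        raise ValueError(f"{p}: text audio needs an explicit sample_rate")
    return read_text_audio(p, sample_rate)


def write_marker_table(tidy: pd.DataFrame, path: str | os.PathLike) -> None:
    missing = [c for c in MARKER_TABLE_COLUMNS if c not in tidy.columns]
    if missing:
        raise ValueError(f"marker table lacks columns {missing}")
    tidy.loc[:, list(MARKER_TABLE_COLUMNS)].to_csv(path, index=False)


def read_marker_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MARKER_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} lacks marker-table columns {missing}")
    return df


def write_madrs_table(madrs: pd.DataFrame, path: str | os.PathLike) -> None:
    madrs.to_csv(path, index=False)


def read_madrs_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("subject_id", "study_day", "madrs"):
        if col not in df.columns:
            raise ValueError(f"{path} lacks MADRS column '{col}'")
    return df


def _result_sort_key(row: AnovaResult) -> tuple[int, int]:
    cond = list(STIMULUS_CLASSES) + ["n/a"]
    cat = list(MARKER_CATALOG) + ["madrs"]
    ci = cond.index(row.condition) if row.condition in cond else len(cond)
    mi = cat.index(row.marker) if row.marker in cat else len(cat)
    return ci, mi


def results_to_frame(results: list[AnovaResult]) -> pd.DataFrame:
    rows = []
    for r in sorted(results, key=_result_sort_key):
        rows.append(
            {
                "condition": r.condition,
                "marker": r.marker,
                "n": r.n,
                "sphericity": "T" if r.sphericity_ok else "F",
                "statistic_kind": r.statistic_kind,
                "statistic": r.statistic,
                "df_num": r.df_num,
                "df_den": r.df_den,
                "p_raw": r.p_raw,
                "p_fdr": r.p_fdr,
                "direction": r.direction,
                "mauchly_w": r.mauchly_w,
                "mauchly_p": r.mauchly_p,
                "f_stat": r.f_stat,
                "f_p": r.f_p,
                "gg_eps": r.gg_eps,
                "gg_p": r.gg_p,
            }
        )
    return pd.DataFrame(rows, columns=list(RESULTS_COLUMNS))


def write_results_table(results: list[AnovaResult], path: str | os.PathLike) -> None:
    """Write the omnibus results table with a deterministic row order.

    Rows are ordered by condition (neutral, positive, negative, n/a) then by
    the fixed marker catalog.  Refuses an empty result list.
    """
    if not results:
        raise ValueError("refusing to write an empty results table")
    try:
        results_to_frame(results).to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"failed writing results table to {path}: {exc}") from exc


def read_results_table(path: str | os.PathLike) -> pd.DataFrame:
    # "n/a" is a literal direction/condition token, not missing data
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    missing = [c for c in RESULTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} lacks results columns {missing}")
    return df


def write_pairwise_table(results: list[AnovaResult], path: str | os.PathLike) -> None:
    rows = []
    for r in sorted(results, key=_result_sort_key):
        for c in r.pairwise:
            rows.append(
                {
                    "condition": r.condition,
                    "marker": r.marker,
                    "contrast": c.contrast,
                    "estimate": c.estimate,
                    "q": c.q,
                    "p_tukey": c.p_tukey,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
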