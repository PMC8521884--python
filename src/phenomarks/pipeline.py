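"""End-to-end stages: simulate -> extract -> analyze -> report.

The single inter-stage contract is the tidy marker table
(``subject_id, study_day, stimulus_class, marker, value``): ``extract`` turns
raw per-response face CSVs and audio into it, ``analyze`` consumes it together
with the MADRS table and writes the omnibus and pairwise results tables.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .catalog import MARKER_CATALOG, STIMULUS_CLASSES
from .config import RunConfig, save_config
from .facial import facial_marker_row, filter_valid_frames
from .longitudinal import (
    AnovaResult,
    VisitMatrix,
    aggregate_and_filter,
    analyze_condition,
    analyze_marker,
    assign_bin,
    minmax_normalize,
)
from .movement import movement_marker_row
from .synthetic import CohortDataset, simulate_cohort
from .voice import voice_marker

log = logging.getLogger("phenomarks")


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def simulate_to_dir(config: RunConfig, out_dir: str | Path) -> Path:
    """Render a full synthetic study to ``out_dir``.

    Writes the effective config, MADRS table, stimulus pool, sequence
    manifests, and one face CSV + one WAV per stimulus response, plus a
    ``manifest.csv`` indexing every response.
    """
    out = Path(out_dir)
    (out / "assessments").mkdir(parents=True, exist_ok=True)
    dataset = simulate_cohort(config.cohort)
    save_config(config, out / "config.yaml")
    pio.write_madrs_table(dataset.madrs, out / "madrs.csv")
    dataset.pool.to_csv(out / "stimulus_pool.csv", index=False)
    dataset.sequence_table().to_csv(out / "sequences.csv", index=False)

    manifest_rows = []
    for rec in dataset.iter_records():
        stem = f"{rec.subject_id}_day{rec.study_day:02d}_pos{rec.position:02d}_{rec.stimulus_class}"
        face_path = out / "assessments" / f"{stem}_face.csv"
        audio_path = out / "assessments" / f"{stem}_audio.wav"
        pio.write_openface_csv(rec.frames, face_path)
        pio.write_wav(rec.audio.samples, rec.audio.sample_rate, audio_path)
        manifest_rows.append(
            {
                "subject_id": rec.subject_id,
                "study_day": rec.study_day,
                "position": rec.position,
                "stimulus_id": rec.stimulus_id,
                "stimulus_class": rec.stimulus_class,
                "face_path": str(face_path.relative_to(out)),
                "audio_path": str(audio_path.relative_to(out)),
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    log.info("simulated study: %d subjects, %d responses -> %s",
             config.cohort.n_subjects, len(manifest), out)
    return out


# ---------------------------------------------------------------------------
# extract
# ---------------------------------------------------------------------------

def extract_markers_for_response(
    frames: pd.DataFrame,
    audio: np.ndarray,
    sample_rate: int,
    min_confidence: float = 0.70,
) -> dict[str, float]:
    """All 17 markers for one stimulus response."""
    row = facial_marker_row(frames, min_confidence=min_confidence)
    valid = filter_valid_frames(frames, min_confidence)
    row.update(movement_marker_row(valid))
    row["voice_percentage"] = voice_marker(audio, sample_rate)
    return row


def extract_from_dir(study_dir: str | Path, config: RunConfig | None = None) -> pd.DataFrame:
    """Build the tidy marker table from a rendered study directory."""
    config = config or RunConfig()
    study = Path(study_dir)
    manifest = pd.read_csv(study / "manifest.csv")
    rows = []
    for rec in manifest.itertuples(index=False):
        frames = pio.read_openface_csv(study / rec.face_path)
        audio, rate = pio.read_audio(study / rec.audio_path)
        markers = extract_markers_for_response(
            frames, audio, rate, min_confidence=config.min_confidence
        )
        for marker in MARKER_CATALOG:
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "study_day": int(rec.study_day),
                    "stimulus_class": rec.stimulus_class,
                    "marker": marker,
                    "value": markers[marker],
                }
            )
    tidy = pd.DataFrame(rows)
    log.info("extracted %d marker values from %d responses", len(tidy), len(manifest))
    return tidy


def extract_from_dataset(dataset: CohortDataset, config: RunConfig | None = None) -> pd.DataFrame:
    """Tidy marker table straight from an in-memory rendered cohort."""
    config = config or RunConfig()
    rows = []
    for rec in dataset.iter_records():
        markers = extract_markers_for_response(
            rec.frames, rec.audio.samples, rec.audio.sample_rate,
            min_confidence=config.min_confidence,
        )
        for marker in MARKER_CATALOG:
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "study_day": rec.study_day,
                    "stimulus_class": rec.stimulus_class,
                    "marker": marker,
                    "value": markers[marker],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------

def madrs_visit_matrix(madrs: pd.DataFrame, min_subjects: int = 2) -> VisitMatrix:
    """Complete-case subject x visit matrix of MADRS totals."""
    tidy = madrs.rename(columns={"madrs": "value"}).assign(
        marker="madrs", stimulus_class="n/a"
    )
    return aggregate_and_filter(tidy, "madrs", None, min_subjects=min_subjects)


def analyze_study(
    tidy: pd.DataFrame,
    madrs: pd.DataFrame | None,
    config: RunConfig | None = None,
) -> list[AnovaResult]:
    """Run the repeated-measures analysis for every marker and condition.

    The FDR family is per stimulus condition by default
    (``config.fdr_family == "condition"``) or the whole table
    (``"table"``).  A MADRS row (condition ``n/a``) is appended when a MADRS
    table is supplied; it forms its own single-test family.
    """
    config = config or RunConfig()
    results: list[AnovaResult] = []
    if config.fdr_family == "table":
        all_res: list[AnovaResult] = []
        deltas: list[float] = []
        from .longitudinal import analyze_family

        for cls in STIMULUS_CLASSES:
            res = analyze_condition(
                tidy, MARKER_CATALOG, cls,
                alpha=config.alpha, sphericity_alpha=config.sphericity_alpha,
            )
            # analyze_condition already set per-condition FDR; recompute table-wide
            all_res.extend(res)
        deltas = [
            float(
                aggregate_and_filter(tidy, r.marker, r.condition).values["week4"].mean()
                - aggregate_and_filter(tidy, r.marker, r.condition).values["baseline"].mean()
            )
            for r in all_res
        ]
        analyze_family(all_res, deltas, alpha=config.alpha)
        results.extend(all_res)
    else:
        for cls in STIMULUS_CLASSES:
            results.extend(
                analyze_condition(
                    tidy, MARKER_CATALOG, cls,
                    alpha=config.alpha, sphericity_alpha=config.sphericity_alpha,
                )
            )
    if madrs is not None:
        vm = madrs_visit_matrix(madrs)
        vm.marker, vm.condition = "madrs", "n/a"
        res = analyze_marker(vm, sphericity_alpha=config.sphericity_alpha)
        res.p_fdr = res.p_raw
        delta = float(vm.values["week4"].mean() - vm.values["baseline"].mean())
        res.direction = ("+" if delta >= 0 else "-") if res.p_fdr < config.alpha else "n/a"
        results.append(res)
    log.info("analyzed %d marker/condition cells", len(results))
    return results


def analyze_to_dir(
    tidy: pd.DataFrame,
    madrs: pd.DataFrame | None,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> list[AnovaResult]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = analyze_study(tidy, madrs, config)
    pio.write_results_table(results, out / "results.csv")
    pio.write_pairwise_table(results, out / "pairwise.csv")
    return results


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

REPORT_MARKERS = ("overall_expressivity", "voice_percentage", "head_movement_mean")


def report_trajectories(
    tidy: pd.DataFrame,
    madrs: pd.DataFrame | None,
    out_path: str | Path,
    markers: tuple[str, ...] = REPORT_MARKERS,
    condition: str = "neutral",
) -> Path:
    """Figure of 0-1 normalized mean +/- SEM visit trajectories (plot-only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels: list[tuple[str, VisitMatrix]] = []
    if madrs is not None:
        panels.append(("MADRS", minmax_normalize(madrs_visit_matrix(madrs))))
    for m in markers:
        try:
            panels.append((m, minmax_normalize(aggregate_and_filter(tidy, m, condition))))
        except ValueError:
            continue
    fig, axes = plt.subplots(1, len(panels), figsize=(3.2 * len(panels), 3.0), squeeze=False)
    for ax, (title, vm) in zip(axes[0], panels):
        means = vm.values.mean()
        sems = vm.values.sem()
        x = np.arange(len(means))
        ax.errorbar(x, means.to_numpy(), yerr=sems.to_numpy(), marker="o", capsize=3)
        ax.set_xticks(x, list(vm.values.columns))
        ax.set_ylim(-0.05, 1.05)
        ax.set_title(f"{title} (n={vm.n})", fontsize=9)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
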