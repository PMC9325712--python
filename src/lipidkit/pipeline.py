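"""Stage orchestration with manifest output.

Each ``run_*`` function executes one stage (simulate, annotate, flux,
profile, diff, image) on files in an output directory; ``run`` dispatches
and assembles a JSON manifest with input/output checksums and per-stage
record counts.  All randomness flows from the single seed in the run
configuration; data outputs are byte-identical across reruns of the same
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import PeakList, Tolerance, annotate_peaks, annotations_to_frame
from .imaging import MarkerWindow, marker_image, roi_summaries_table, tic_normalize
from .io import read_table
from .isotope import IsotopologueVector, correct_and_ratio
from .profiles import LipidTable, class_totals, double_bond_profile_tidy
from .registry import DEFAULT_ADDUCTS, load_registry
from .simulate import SimConfig, simulate_ion_image, simulate_lipid_table, simulate_peaklist, simulate_isotopologues
from .stats import differential_table

__all__ = ["RunConfig", "RunManifest", "run"]

SUBCOMMANDS = ("simulate", "annotate", "flux", "profile", "diff", "image", "all")


@dataclass
class RunConfig:
    """Validated pipeline run configuration."""

    subcommand: str
    out_dir: Path
    seed: int = 0
    registry_path: Path | None = None
    peaks_path: Path | None = None
    isotopologues_path: Path | None = None
    table_path: Path | None = None
    meta_path: Path | None = None
    tolerance: Tolerance = field(default_factory=Tolerance.imaging)
    q: float = 0.05
    contrast: tuple[str, str] = ("KM", "healthy")
    contrast_on: str = "group"
    preset: str | None = "fig1_km"
    sim: SimConfig | None = None

    def __post_init__(self) -> None:
        if self.subcommand not in SUBCOMMANDS:
            raise ValueError(
                f"unknown subcommand {self.subcommand!r}; known: {SUBCOMMANDS}"
            )
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        for name in ("registry_path", "peaks_path", "isotopologues_path",
                     "table_path", "meta_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"configuration field {name}: path {p} does not exist")


@dataclass
class RunManifest:
    version: str
    subcommand: str
    seed: int
    config: dict
    inputs: dict[str, str]
    outputs: dict[str, str]
    record_counts: dict[str, int]
    warnings: list[str]
    failed_stage: str | None
    started: str
    finished: str

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sim_config(cfg: RunConfig) -> SimConfig:
    sim = cfg.sim if cfg.sim is not None else SimConfig(seed=cfg.seed)
    sim = dataclasses.replace(sim, seed=cfg.seed)
    if cfg.preset:
        sim = sim.with_effects(cfg.preset)
    return sim


def _stage_simulate(cfg: RunConfig, out: Path, counts: dict) -> None:
    sim = _sim_config(cfg)
    table, truth = simulate_lipid_table(sim)
    table.to_tsv(out / "lipid_table.tsv", out / "sample_meta.tsv")
    truth.effects.rename_axis("species_id").to_csv(out / "ground_truth_effects.tsv", sep="\t")
    vectors, iso_truth = simulate_isotopologues(sim)
    rows = []
    for rep, vec in vectors:
        for m_plus, intensity in enumerate(vec.intensities):
            rows.append(
                {"analyte_id": vec.analyte_id, "n_carbons": vec.n_carbons,
                 "m_plus": m_plus, "intensity": intensity, "sample_id": rep}
            )
    pd.DataFrame(rows).to_csv(out / "isotopologues.csv", index=False)
    (out / "ground_truth_fractions.json").write_text(
        json.dumps(iso_truth.labeled_fractions, indent=2)
    )
    peaks, peak_truth = simulate_peaklist(sim)
    pd.DataFrame(
        {"mz": peaks.mz, "intensity": peaks.intensity,
         "polarity": peaks.polarity}
    ).to_csv(out / "peaks.csv", index=False)
    (out / "ground_truth_peaks.json").write_text(
        json.dumps(peak_truth.peak_identities, indent=2)
    )
    grid, masks, img_truth = simulate_ion_image(sim)
    grid.save(out / "ion_image")
    label = np.zeros(grid.shape, dtype=int)
    for i, m in enumerate(masks, start=1):
        label[m.mask] = i
    np.savetxt(out / "roi_labels.csv", label, delimiter=",", fmt="%d")
    (out / "ground_truth_markers.json").write_text(
        json.dumps(img_truth.marker_contrast, indent=2)
    )
    counts["simulate.species"] = table.abundances.shape[0]
    counts["simulate.samples"] = table.abundances.shape[1]
    counts["simulate.peaks"] = int(peaks.mz.size)
    counts["simulate.isotopologue_rows"] = len(rows)
    counts["simulate.image_pixels"] = int(np.prod(grid.shape))


def _stage_annotate(cfg: RunConfig, out: Path, counts: dict) -> None:
    peaks_path = cfg.peaks_path or out / "peaks.csv"
    df = read_table(peaks_path, "peaks")
    from .simulate import default_registry

    registry = (
        load_registry(cfg.registry_path) if cfg.registry_path else default_registry()
    )
    polarity = df["polarity"].iloc[0]
    peaks = PeakList(polarity, df["mz"].to_numpy(), df["intensity"].to_numpy())
    anns = annotate_peaks(peaks, registry, DEFAULT_ADDUCTS, cfg.tolerance)
    frame = annotations_to_frame(peaks, anns)
    frame.to_csv(out / "annotations.tsv", sep="\t", index=False)
    counts["annotate.peaks"] = len(frame)
    counts["annotate.matched"] = int((frame["species_id"] != "").sum())


def _stage_flux(cfg: RunConfig, out: Path, counts: dict) -> None:
    iso_path = cfg.isotopologues_path or out / "isotopologues.csv"
    df = read_table(iso_path, "isotopologues")
    rows = []
    for (analyte, sample), sub in df.groupby(["analyte_id", "sample_id"]):
        sub = sub.sort_values("m_plus")
        vec = IsotopologueVector(
            analyte, int(sub["n_carbons"].iloc[0]), sub["intensity"].to_numpy()
        )
        res = correct_and_ratio(vec)
        row = {"analyte_id": analyte, "sample_id": sample}
        row.update({f"f{i}": v for i, v in enumerate(res.fractions)})
        row["m2_over_m0"] = res.ratios.m2_over_m0
        row["m4_over_m0"] = res.ratios.m4_over_m0
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "flux_ratios.tsv", sep="\t", index=False)
    counts["flux.analytes"] = len(rows)


def _load_table(cfg: RunConfig, out: Path) -> LipidTable:
    table_path = cfg.table_path or out / "lipid_table.tsv"
    meta_path = cfg.meta_path or out / "sample_meta.tsv"
    ab = read_table(table_path, "lipid_table")
    meta = read_table(meta_path, "sample_meta")
    return LipidTable(ab, meta, normalized=True)


def _stage_profile(cfg: RunConfig, out: Path, counts: dict) -> None:
    table = _load_table(cfg, out)
    totals = class_totals(table)
    totals.rename_axis("class").to_csv(out / "class_totals.tsv", sep="\t")
    tidy = double_bond_profile_tidy(table)
    tidy.to_csv(out / "double_bond_profile.tsv", sep="\t", index=False)
    counts["profile.classes"] = totals.shape[0]
    counts["profile.rows"] = len(tidy)


def _stage_diff(cfg: RunConfig, out: Path, counts: dict) -> None:
    table = _load_table(cfg, out)
    level, reference = cfg.contrast
    cols_a = table.samples_where(**{cfg.contrast_on: level})
    cols_b = table.samples_where(**{cfg.contrast_on: reference})
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"contrast {cfg.contrast} on {cfg.contrast_on!r} needs >= 2 samples "
            f"per level (got {len(cols_a)}, {len(cols_b)})"
        )
    species_diff = differential_table(table.abundances, cols_a, cols_b, q=cfg.q)
    species_diff.rename_axis("feature").to_csv(out / "differential_species.tsv", sep="\t")
    totals = class_totals(table)
    class_diff = differential_table(totals, cols_a, cols_b, q=cfg.q,
                                    log_transform=False)
    class_diff.rename_axis("feature").to_csv(out / "differential_classes.tsv", sep="\t")
    counts["diff.species"] = len(species_diff)
    counts["diff.classes"] = len(class_diff)
    counts["diff.significant_species"] = int(species_diff["significant"].sum())


def _stage_image(cfg: RunConfig, out: Path, counts: dict) -> None:
    from .imaging import ROIMask, SpectrumGrid

    grid = SpectrumGrid.load(out / "ion_image")
    label = np.loadtxt(out / "roi_labels.csv", delimiter=",", dtype=int)
    masks = [ROIMask(name, label == i) for i, name in ((1, "T"), (2, "S"))
             if (label == i).any()]
    truth_path = out / "ground_truth_markers.json"
    if truth_path.exists():
        marker_info = json.loads(truth_path.read_text())
        windows = {name: MarkerWindow(info["mz"]) for name, info in marker_info.items()}
    else:
        raise ValueError(
            "image stage needs marker definitions (ground_truth_markers.json)"
        )
    norm, n_zero = tic_normalize(grid)
    raw_markers = {n: marker_image(grid, w) for n, w in windows.items()}
    pct_markers = {n: marker_image(norm, w) for n, w in windows.items()}
    raw_tab = roi_summaries_table(raw_markers, masks, grid.pixel_size_um)
    pct_tab = roi_summaries_table(pct_markers, masks, grid.pixel_size_um)
    raw_tab.insert(0, "scale", "raw")
    pct_tab.insert(0, "scale", "pct_tic")
    pd.concat([raw_tab, pct_tab], ignore_index=True).to_csv(
        out / "roi_summaries.tsv", sep="\t", index=False
    )
    counts["image.markers"] = len(windows)
    counts["image.rois"] = len(masks)
    counts["image.zero_tic_pixels"] = n_zero


_STAGES = {
    "simulate": _stage_simulate,
    "annotate": _stage_annotate,
    "flux": _stage_flux,
    "profile": _stage_profile,
    "diff": _stage_diff,
    "image": _stage_image,
}


def run(config: RunConfig) -> RunManifest:
    """Execute a subcommand (or ``all``) and write ``manifest.json``.

    Stages run in dependency order; on failure the manifest records the
    failed stage and partial outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    counts: dict[str, int] = {}
    warnings_log: list[str] = []
    failed: str | None = None
    if config.subcommand == "all":
        stages = ["simulate", "annotate", "flux", "profile", "diff", "image"]
        if config.table_path is not None:
            stages.remove("simulate")
    else:
        stages = [config.subcommand]
    inputs = {
        str(p): _sha256(Path(p))
        for p in (config.registry_path, config.peaks_path, config.table_path,
                  config.meta_path, config.isotopologues_path)
        if p is not None
    }
    try:
        import warnings as _w

        with _w.catch_warnings(record=True) as caught:
            _w.simplefilter("always")
            for stage in stages:
                _STAGES[stage](config, out, counts)
        warnings_log = [str(w.message) for w in caught]
    except Exception as exc:
        failed = f"{stage}: {exc}"
    outputs = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        version=__version__,
        subcommand=config.subcommand,
        seed=config.seed,
        config={
            "q": config.q,
            "tolerance": dataclasses.asdict(config.tolerance),
            "contrast": list(config.contrast),
            "contrast_on": config.contrast_on,
            "preset": config.preset,
        },
        inputs=inputs,
        outputs=outputs,
        record_counts=counts,
        warnings=warnings_log,
        failed_stage=failed,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(out / "manifest.json")
    if failed is not None:
        raise RuntimeError(f"pipeline stage failed ({failed}); manifest written")
    return manifest
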