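"""Orchestration: phantom/volume -> mask -> thickness -> S(w) -> model -> V.

One :class:`RunConfig` drives the whole chain; every stage writes its
artifact into the output directory and the run ends with a single JSON
report (config echo, segmentation thresholds, anchors, model, V and the
physical volume, optional rank statistics). All randomness flows from the
single config seed through a documented ``numpy`` SeedSequence split
(stream 0: phantom generation), so identical configs produce identical
reports.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io
from .distribution import area_width_distribution, extract_anchors, thickness_weighted_volume
from .phantom import generate_phantom, group_preset, preset_bin_width
from .segmentation import SegmentationConfig, segment_adhesive
from .swmodel import fit_model, integrate_model, select_template
from .thickness import local_thickness


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (a TIFF/MetaImage volume) or
    ``phantom_group`` (1-4, synthetic preset) must be given. ``template``
    is "A", "B" or "auto" (A when the peak width wM >= 0.05 mm).
    """

    output_dir: str
    input_path: str | None = None
    phantom_group: int | None = None
    seed: int = 0
    intensity_band: tuple[float, float] | None = None
    bin_width: float | None = None  # None: 0.01 mm, or 0.002 for narrow presets
    smoothing_window: int = 3
    template: str = "auto"
    n_section_points: int = 10
    run_stats: bool = False
    overwrite: bool = False
    write_artifacts: bool = True

    def validate(self) -> None:
        if (self.input_path is None) == (self.phantom_group is None):
            raise ConfigError("exactly one of input_path or phantom_group is required")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ConfigError(f"input path does not exist: {self.input_path}")
        if self.phantom_group is not None and self.phantom_group not in (1, 2, 3, 4):
            raise ConfigError(f"phantom_group must be 1-4, got {self.phantom_group}")
        if self.template not in ("A", "B", "auto"):
            raise ConfigError(f"template must be A, B or auto, got {self.template!r}")
        if self.bin_width is not None and self.bin_width <= 0:
            raise ConfigError("bin_width must be > 0")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ConfigError("smoothing_window must be a positive odd integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "intensity_band" in data and data["intensity_band"] is not None:
            data["intensity_band"] = tuple(data["intensity_band"])
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and return (and write) the run report."""
    config.validate()
    out = Path(config.output_dir)
    report_path = out / "report.json"
    if report_path.exists() and not config.overwrite:
        raise ConfigError(
            f"output report already exists: {report_path} (set overwrite to rerun)"
        )
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "config": _config_echo(config),
    }

    truth = None
    if config.phantom_group is not None:
        spec = group_preset(config.phantom_group, seed=_stage_seed(config.seed, 0))
        volume, truth = generate_phantom(spec)
        report["phantom"] = {
            "group": config.phantom_group,
            "true_volume_mm3": truth.true_volume,
            "voxel_size_mm": spec.voxel_size,
            "grid_shape": list(spec.grid_shape),
        }
        default_bin = preset_bin_width(spec)
        if config.write_artifacts:
            io.write_volume(out / "volume.tif", volume)
            io.write_mask(out / "truth_mask.tif", truth.mask)
    else:
        volume = io.read_volume(config.input_path)
        default_bin = 0.01

    seg_cfg = SegmentationConfig(intensity_band=config.intensity_band)
    mask, seg_report = segment_adhesive(volume, seg_cfg)
    report["segmentation"] = seg_report
    if truth is not None:
        inter = np.logical_and(mask.mask, truth.mask.mask).sum()
        report["segmentation"]["dice_vs_truth"] = float(
            2.0 * inter / (mask.voxel_count + truth.mask.voxel_count)
        )
    if config.write_artifacts:
        io.write_mask(out / "adhesive_mask.tif", mask)

    tmap = local_thickness(mask)
    if config.write_artifacts:
        io.write_thickness_map(out / "thickness_mm.tif", tmap)

    bin_width = config.bin_width if config.bin_width is not None else default_bin
    dist = area_width_distribution(mask, tmap, bin_width=bin_width)
    anchors = extract_anchors(dist, smoothing_window=config.smoothing_window)
    template = (
        select_template(anchors) if config.template == "auto" else config.template
    )
    model = fit_model(dist, template, anchors)
    vstat = integrate_model(model, group=str(config.phantom_group or "input"))

    report["distribution"] = {
        "bin_width_mm": bin_width,
        "total_area_mm2": dist.total_area,
        "occupied_bins": int(dist.occupied().sum()),
        "argmax_width_mm": float(dist.bin_centers[int(np.argmax(dist.areas))]),
    }
    report["anchors"] = anchors.to_dict()
    report["model"] = model.to_dict()
    report["V_paper_mm3"] = vstat.V
    report["physical_volume_mm3"] = thickness_weighted_volume(dist)
    if config.write_artifacts:
        dist.to_frame().to_csv(out / "distribution.csv", index=False)

    if config.run_stats:
        report["stats"] = _fixture_stats()

    io.write_json(report_path, report)
    return report


def run_group_comparison(
    output_dir: str | Path,
    seed: int = 0,
    groups=(1, 2, 3, 4),
    write_artifacts: bool = False,
) -> dict:
    """Full pipeline on every group preset plus the volume-ordering report."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports = {}
    for g in groups:
        cfg = RunConfig(
            output_dir=str(out / f"group{g}"),
            phantom_group=g,
            seed=seed,
            overwrite=True,
            write_artifacts=write_artifacts,
        )
        reports[g] = run_pipeline(cfg)
    volumes = {g: r["V_paper_mm3"] for g, r in reports.items()}
    physical = {g: r["physical_volume_mm3"] for g, r in reports.items()}
    ordered = sorted(groups)
    summary = {
        "seed": seed,
        "V_paper_mm3": {str(g): volumes[g] for g in ordered},
        "physical_volume_mm3": {str(g): physical[g] for g in ordered},
        "V_strictly_decreasing": all(
            volumes[a] > volumes[b] for a, b in zip(ordered, ordered[1:])
        ),
        "physical_strictly_decreasing": all(
            physical[a] > physical[b] for a, b in zip(ordered, ordered[1:])
        ),
    }
    io.write_json(out / "comparison.json", summary)
    return summary


def _stage_seed(seed: int, stream: int) -> int:
    """Derive one deterministic 31-bit sub-seed per pipeline stage."""
    child = np.random.SeedSequence(seed).spawn(stream + 1)[stream]
    return int(child.generate_state(1, np.uint64)[0] % (2**31))


def _config_echo(config: RunConfig) -> dict:
    echo = asdict(config)
    echo["intensity_band"] = (
        list(config.intensity_band) if config.intensity_band else None
    )
    return echo


def _fixture_stats() -> dict:
    """Method and group comparisons on the packaged per-sample width table."""
    from .phantom import load_table1_fixture
    from .stats import mann_whitney_u, select_widths, wilcoxon_signed_rank

    records = load_table1_fixture()
    out = {"wilcoxon_microscopy_vs_microct": {}, "mann_whitney_between_groups": {}}
    for area in ("vestibular", "oral", "pulpal"):
        a = select_widths(records, method="microscopy", area=area)
        b = select_widths(records, method="microct", area=area)
        out["wilcoxon_microscopy_vs_microct"][area] = wilcoxon_signed_rank(a, b).to_dict()
    for ga, gb in ((1, 2), (1, 3), (3, 4)):
        a = select_widths(records, group=ga, method="microct")
        b = select_widths(records, group=gb, method="microct")
        out["mann_whitney_between_groups"][f"{ga}_vs_{gb}"] = mann_whitney_u(a, b).to_dict()
    return out
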