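"""Run orchestration: reproducible analysis stages with provenance.

Each run writes a resolved configuration (with version, timestamp, and input
hashes) alongside a JSON analysis report keyed by stage.  The report itself
carries no timestamp, so identical configurations and seeds produce
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__, datasets
from .geometry import (
    Segment2D,
    Point2D,
    build_voronoi,
    duality_angles,
    parse_seed_coordinates,
    tessellation_congruence,
    wall_vs_delaunay_angles,
)
from .morphometry import (
    BinaryMask,
    GrayImage,
    MorphometryReport,
    area_fraction,
    binarize,
    cell_major_axis,
    measure_layer_thickness,
    measure_pore_geometry,
    preprocess,
)
from .stats import band_ratios, percent_reduction, student_t_test, summarize
from .synthetic import (
    CapsuleParams,
    RenderParams,
    perturb_walls,
    render_annular_layer,
    render_biofilm_section,
    render_capsule_cross_section,
    render_cell_surface,
    sample_pore_centers,
    synth_spectrum,
)

__all__ = [
    "PipelineError",
    "run_voronoi_verification",
    "run_morphometry",
    "run_full_demo",
    "load_wall_segments_csv",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_json(obj: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _write_config(out_dir: Path, config: dict, inputs: dict[str, Path]) -> None:
    resolved = {
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config,
        "input_hashes": {name: _sha256(p) for name, p in inputs.items() if p is not None},
    }
    _write_json(resolved, Path(out_dir) / "config.json")


def load_wall_segments_csv(path: Path) -> list[Segment2D]:
    """Wall segments from a CSV with header ``x1,y1,x2,y2``."""
    import pandas as pd

    df = pd.read_csv(path)
    expected = ["x1", "y1", "x2", "y2"]
    if list(df.columns) != expected:
        raise PipelineError(f"walls CSV must have header {','.join(expected)}")
    return [
        Segment2D(Point2D(r.x1, r.y1), Point2D(r.x2, r.y2))
        for r in df.itertuples(index=False)
    ]


def _overlay_figure(tess, walls, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    for seg in tess.edge_segments:
        ax.plot([seg.a.x, seg.b.x], [seg.a.y, seg.b.y], "k-", lw=1.2)
    for seg, _ in tess.delaunay_edges:
        ax.plot([seg.a.x, seg.b.x], [seg.a.y, seg.b.y], "g-", lw=0.6, alpha=0.6)
    pts = tess.seeds.points
    ax.plot(pts[:, 0], pts[:, 1], "bo", ms=3)
    if walls:
        for seg in walls:
            ax.plot([seg.a.x, seg.b.x], [seg.a.y, seg.b.y], "r-", lw=1.0, alpha=0.8)
    ax.set_aspect("equal")
    ax.set_title("computed diagram (black), Delaunay (green), observed walls (red)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def run_voronoi_verification(
    seeds_path: Path | None,
    walls_path: Path | None,
    out_dir: Path,
    congruence_tolerance: float = 10.0,
    make_figure: bool = True,
) -> dict:
    """Build the tessellation from a seed listing (bundled P1-P22 fixture when
    ``seeds_path`` is None), verify edge/dual perpendicularity, and — when a
    traced wall network is given — score it against the computed ideal."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        if seeds_path is None:
            seeds = datasets.capsule_seed_points()
        else:
            seeds = parse_seed_coordinates(Path(seeds_path).read_text(encoding="utf-8"))
    except Exception as exc:
        raise PipelineError(f"seed parsing: {exc}") from exc
    try:
        tess = build_voronoi(seeds)
        report: dict = {
            "n_sites": len(seeds),
            "n_voronoi_edges": len(tess.edges),
            "duality_angles": duality_angles(tess).to_dict(),
        }
    except Exception as exc:
        raise PipelineError(f"voronoi construction: {exc}") from exc
    walls = None
    if walls_path is not None:
        try:
            walls = load_wall_segments_csv(Path(walls_path))
            report["wall_vs_delaunay_angles"] = wall_vs_delaunay_angles(
                walls, seeds
            ).to_dict()
            report["congruence"] = tessellation_congruence(
                walls, tess, tolerance=congruence_tolerance
            ).to_dict()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"wall comparison: {exc}") from exc
    if make_figure:
        _overlay_figure(tess, walls, out_dir / "overlay.png")
    _write_json(report, out_dir / "report.json")
    _write_config(
        out_dir,
        {
            "stage": "voronoi",
            "seeds": str(seeds_path) if seeds_path else "bundled:capsule_seed_points",
            "walls": str(walls_path) if walls_path else None,
            "congruence_tolerance": congruence_tolerance,
        },
        {"seeds": seeds_path, "walls": walls_path},
    )
    return report


def run_morphometry(
    image_path: Path,
    out_dir: Path,
    nm_per_px: float,
    measure: str = "area_fraction",
    edge_emphasis: bool = False,
    smoothing_scale: float = 1.5,
    threshold: float | None = None,
    foreground: str = "bright",
) -> dict:
    """Segment a calibrated image and run the requested measurement
    (``area_fraction``, ``pore_diameter``, ``pore_depth``,
    ``capsule_thickness``, ``cell_wall_thickness``, or ``cell_major_axis``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image_path = Path(image_path)
    if not image_path.exists():
        raise PipelineError(f"input image: no such file {image_path}")
    try:
        img = GrayImage.load(image_path, nm_per_px)
    except Exception as exc:
        raise PipelineError(f"image loading: {exc}") from exc
    try:
        pre = preprocess(img, edge_emphasis=edge_emphasis, smoothing_scale=smoothing_scale)
        mask = binarize(
            pre,
            method="otsu" if threshold is None else "fixed",
            level=threshold,
            foreground=foreground,
        )
    except Exception as exc:
        raise PipelineError(f"segmentation: {exc}") from exc
    report: dict = {"nm_per_px": nm_per_px}
    try:
        fg, bg = area_fraction(mask)
        report["area_fraction"] = {"foreground_pct": fg, "background_pct": bg}
        if measure == "pore_diameter":
            report["morphometry"] = measure_pore_geometry(mask, mode="horizontal").to_dict()
        elif measure == "pore_depth":
            report["morphometry"] = measure_pore_geometry(mask, mode="vertical").to_dict()
        elif measure in ("capsule_thickness", "cell_wall_thickness"):
            report["morphometry"] = measure_layer_thickness(mask, kind=measure).to_dict()
        elif measure == "cell_major_axis":
            report["morphometry"] = cell_major_axis(mask).to_dict()
        elif measure != "area_fraction":
            raise PipelineError(f"unknown measurement {measure!r}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"measurement ({measure}): {exc}") from exc
    mask.save(out_dir / "mask.png")
    _write_json(report, out_dir / "report.json")
    if "morphometry" in report:
        import pandas as pd

        rows = [
            {"kind": k, **v} for k, v in report["morphometry"].items()
        ]
        pd.DataFrame(rows).to_csv(out_dir / "morphometry.csv", index=False)
    _write_config(
        out_dir,
        {
            "stage": "segment",
            "image": str(image_path),
            "nm_per_px": nm_per_px,
            "measure": measure,
            "edge_emphasis": edge_emphasis,
            "smoothing_scale": smoothing_scale,
            "threshold": threshold,
            "foreground": foreground,
        },
        {"image": image_path},
    )
    return report


def run_full_demo(out_dir: Path, rng_seed: int = 42) -> dict:
    """Generate every synthetic fixture and run the full analysis chain,
    mirroring the study's results order: cell size, biofilm area fraction,
    pore diameter/depth, Voronoi verification, layer thickness, growth-curve
    statistics, and FT-IR band ratios.

    The consolidated report is deterministic for a given seed (no timestamp).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(rng_seed)
    seeds = [int(s) for s in ss.generate_state(8) % (2**31)]
    params = CapsuleParams()
    report: dict = {"rng_seed": rng_seed}

    # 1. cell size on the biofilm surface (n = 40 cells)
    cells = render_cell_surface(
        params, n_cells=40, extent=(1100, 1100),
        render=RenderParams(nm_per_px=20.0, noise_sd=0.04, blur_sigma=1.0, rng_seed=seeds[0]),
    )
    mask = binarize(preprocess(cells.image, edge_emphasis=False, smoothing_scale=1.0))
    report["cell_major_axis"] = cell_major_axis(mask).to_dict()["cell_major_axis"]
    report["cell_major_axis"]["true_mean_um"] = float(
        np.mean(cells.truth["cell_diameters_um"])
    )

    # 2. sponge-biofilm cell:cavity area fraction
    biofilm = render_biofilm_section(
        45.3, cell_size_px=60.0, extent=(768, 768),
        render=RenderParams(nm_per_px=10.0, noise_sd=0.05, blur_sigma=1.2, rng_seed=seeds[1]),
    )
    bmask = binarize(preprocess(biofilm.image, edge_emphasis=False, smoothing_scale=1.5))
    fg, bg = area_fraction(bmask)
    report["biofilm_area_fraction"] = {
        "cells_pct": fg,
        "cavities_pct": bg,
        "true_cells_pct": biofilm.truth["cell_fraction_pct"],
    }

    # 3. pore diameter (horizontal capsule section)
    sites = sample_pore_centers(params, extent=(2000.0, 2000.0), rng_seed=seeds[2])
    horiz = render_capsule_cross_section(
        sites, params,
        RenderParams(nm_per_px=2.0, noise_sd=0.05, blur_sigma=1.0, rng_seed=seeds[3]),
        orientation="horizontal",
    )
    hmask = binarize(preprocess(horiz.image, edge_emphasis=False, smoothing_scale=1.0))
    report["pore_diameter"] = measure_pore_geometry(hmask, mode="horizontal").to_dict()[
        "pore_diameter"
    ]

    # 4. pore depth (vertical section)
    vert = render_capsule_cross_section(
        None, params,
        RenderParams(nm_per_px=2.0, noise_sd=0.05, blur_sigma=1.0, rng_seed=seeds[4]),
        orientation="vertical", n_spines=50,
    )
    vmask = binarize(preprocess(vert.image, edge_emphasis=False, smoothing_scale=1.0))
    report["pore_depth"] = measure_pore_geometry(vmask, mode="vertical").to_dict()[
        "pore_depth"
    ]

    # 5. Voronoi verification on the bundled 22-point worked example
    fixture = datasets.capsule_seed_points()
    tess = build_voronoi(fixture)
    report["voronoi_duality"] = duality_angles(tess).to_dict()
    jittered = perturb_walls(tess, angle_jitter_sd=6.0, rng_seed=seeds[5])
    report["traced_wall_angles"] = wall_vs_delaunay_angles(jittered, fixture).to_dict()
    report["congruence_vs_jittered"] = tessellation_congruence(
        jittered, tess, tolerance=10.0
    ).to_dict()

    # 6. capsule layer thickness (annular section)
    ann = render_annular_layer(
        params, RenderParams(nm_per_px=2.0, noise_sd=0.04, blur_sigma=0.8, rng_seed=seeds[6]),
        kind="capsule_thickness",
    )
    amask = binarize(preprocess(ann.image, edge_emphasis=False, smoothing_scale=0.8))
    report["capsule_thickness"] = measure_layer_thickness(
        amask, kind="capsule_thickness"
    ).to_dict()["capsule_thickness"]

    # 7. growth-curve style statistics (synthetic replicates, n = 3 each)
    rng = np.random.default_rng(seeds[7])
    control = rng.normal(1.0, 0.05, 3)
    treated = rng.normal(0.2, 0.05, 3)
    report["t_test_example"] = student_t_test(control, treated).to_dict()
    report["t_test_example"]["summary_control"] = summarize(control).to_dict()
    report["t_test_example"]["summary_treated"] = summarize(treated).to_dict()

    # 8. FT-IR band ratios: copper exposure shrinks amide and C-O bands
    base_peaks = [(3400.0, 80.0, 3.0), (1620.0, 60.0, 2.0), (1075.0, 35.0, 1.5), (2920.0, 40.0, 1.0)]
    control_spec = synth_spectrum(base_peaks, noise_sd=0.0)
    treated_peaks = [
        (3400.0, 80.0, 3.0),
        (1620.0, 60.0, 2.0 * 0.808),
        (1075.0, 35.0, 1.5 * 0.764),
        (2920.0, 40.0, 1.0),
    ]
    treated_spec = synth_spectrum(treated_peaks, noise_sd=0.0)
    rc = band_ratios(control_spec, baseline="none")
    rt = band_ratios(treated_spec, baseline="none")
    report["ftir"] = {
        "control": rc.to_dict(),
        "treated": rt.to_dict(),
        "amide_reduction_pct": percent_reduction(rc.b_over_d, rt.b_over_d),
        "co_reduction_pct": percent_reduction(rc.c_over_d, rt.c_over_d),
    }

    _write_json(report, out_dir / "report.json")
    _write_config(out_dir, {"stage": "demo", "rng_seed": rng_seed}, {})
    return report
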