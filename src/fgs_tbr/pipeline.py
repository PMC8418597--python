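"""End-to-end reproducible run: phantom generation -> TBR analysis ->
pixel classification -> report.

A single :class:`RunConfig` (YAML-loadable) drives every stage.  The run is
a pure function of the config: the config seed fans out to fixed per-stage
child seeds, so identical configs produce byte-identical CSV/JSON outputs.
Outputs land under ``out/{phantoms,tbr,classify,report}``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import phantom as ph
from . import tbr as tbr_mod
from .dataio import load_case

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_pipeline", "write_report"]

# clinically acceptable in vivo signal reference; reported as annotation only
TBR_DETECTABILITY = 1.5


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    n_per_cohort: int = 20
    out_dir: str = "out"
    phantom: dict = field(default_factory=dict)  # PhantomConfig field overrides
    acquisition_context: str = "grossing"
    train_fraction: float = 0.7
    ridge: float = 1e-6
    age_cut_years: float = 60.0
    depth_cut_mm: float = 4.0
    tbr_detectability: float = TBR_DETECTABILITY
    holm: bool = False
    schemes: tuple = ("image_wise", "loocv")
    make_plots: bool = True
    n_overlays: int = 2

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.depth_cut_mm <= 0 or self.age_cut_years <= 0 or self.tbr_detectability <= 0:
            raise ValueError("cut-offs must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "schemes" in data:
            data["schemes"] = tuple(data["schemes"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schemes"] = list(d["schemes"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _phantom_config(config: RunConfig) -> ph.PhantomConfig:
    return dataclasses.replace(ph.PhantomConfig(), **config.phantom)


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the machine-readable report dict.

    Stages: generate phantoms -> reload from disk (validating the I/O round
    trip) -> per-image TBR with exclusions -> cohort/subgroup summaries and
    pixel-level tests -> classifier validation (image-wise and
    leave-one-image-out, per cohort) -> report files.
    """
    out = Path(config.out_dir)
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
    }

    # --- stage 1: phantoms -------------------------------------------------
    try:
        manifest, _ = ph.generate_cohort_dataset(
            config.n_per_cohort,
            base_config=_phantom_config(config),
            seed=config.seed,
            out_dir=out / "phantoms",
            acquisition_context=config.acquisition_context,
        )
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise RuntimeError(f"phantom stage failed: {exc}") from exc

    # --- stage 2: load + TBR ----------------------------------------------
    try:
        cases = [load_case(row, root=out / "phantoms") for _, row in manifest.iterrows()]
        patients = {c.patient.patient_id: c.patient for c in cases}
        results = [
            tbr_mod.compute_tbr(
                c.image, c.mask, image_id=c.image_id, patient_id=c.patient.patient_id
            )
            for c in cases
        ]
        results = tbr_mod.apply_exclusions(results, patients, depth_cut_mm=config.depth_cut_mm)
    except Exception as exc:
        raise RuntimeError(f"TBR stage failed: {exc}") from exc

    tbr_dir = out / "tbr"
    tbr_dir.mkdir(parents=True, exist_ok=True)
    tbr_df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    tbr_df.to_csv(tbr_dir / "tbr_results.csv", index=False, float_format="%.10g")

    exclusion_counts = {reason: 0 for reason in tbr_mod.EXCLUSION_REASONS if reason != "none"}
    for r in results:
        if not r.included:
            exclusion_counts[r.exclusion_reason] += 1
    report["exclusions"] = exclusion_counts

    # --- stage 3: cohort summaries + pixel tests ---------------------------
    included = [r for r in results if r.included]
    cohort_block: dict = {"skipped": False}
    if config.n_per_cohort < 2:
        warnings.warn("fewer than 2 images per cohort; cohort comparison skipped")
        cohort_block["skipped"] = True
        cohort_block["reason"] = "fewer than 2 images per cohort"
    else:
        model = tbr_mod.TBRCohortModel.from_results(included, patients)
        fitted = model.fit(
            age_cut=config.age_cut_years, depth_cut_mm=config.depth_cut_mm, holm=config.holm
        )
        cohort_block.update(fitted.to_dict())
        cohort_block["detectability_reference"] = config.tbr_detectability
        cohort_block["cohorts_above_detectability"] = {
            s.label: bool(s.tbr_mean > config.tbr_detectability)
            for s in fitted.summaries
            if s.label in ("EPR", "ANGIO")
        }
        with open(tbr_dir / "cohort_summary.json", "w") as fh:
            json.dump(cohort_block, fh, indent=2)
    report["tbr"] = cohort_block

    # pixel-level rank-sum per image and pooled per cohort
    try:
        from .dataio import extract_pixel_samples

        pixel_tests: dict = {"per_image": {}, "per_cohort": {}}
        pooled: dict[str, list] = {"EPR": [[], []], "ANGIO": [[], []]}
        included_ids = {r.image_id for r in included}
        for c in cases:
            if c.image_id not in included_ids:
                continue
            tumor, healthy = extract_pixel_samples(c.image, c.mask)
            res = tbr_mod.pixel_level_comparison(tumor, healthy)
            pixel_tests["per_image"][c.image_id] = {
                "p_one_sided_greater": res.p_one_sided_greater,
                "z_value": res.z_value,
            }
            pooled[c.patient.cohort][0].append(tumor)
            pooled[c.patient.cohort][1].append(healthy)
        histograms: dict = {}
        for cohort, (tum, heal) in pooled.items():
            if not tum:
                continue
            t = np.concatenate(tum)
            h = np.concatenate(heal)
            res = tbr_mod.pixel_level_comparison(t, h)
            pixel_tests["per_cohort"][cohort] = {
                "p_one_sided_greater": res.p_one_sided_greater,
                "z_value": res.z_value,
                "n_tumor_px": int(t.size),
                "n_healthy_px": int(h.size),
            }
            edges = np.histogram_bin_edges(np.concatenate([t, h]), bins=50)
            histograms[cohort] = {
                "bin_edges": edges.tolist(),
                "tumor_counts": np.histogram(t, bins=edges)[0].tolist(),
                "healthy_counts": np.histogram(h, bins=edges)[0].tolist(),
            }
            if config.make_plots:
                _plot_histogram(t, h, cohort, tbr_dir / f"pixel_histogram_{cohort}.png")
        pixel_tests["histograms"] = histograms
        report["pixel_tests"] = pixel_tests
    except Exception as exc:
        raise RuntimeError(f"pixel-level test stage failed: {exc}") from exc

    # --- stage 4: classification -------------------------------------------
    try:
        classify_dir = out / "classify"
        classify_dir.mkdir(parents=True, exist_ok=True)
        included_cases = [c for c in cases if c.image_id in included_ids]
        scores: list[clf.ValidationScore] = []
        split_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
        if "image_wise" in config.schemes:
            overlays_done = 0
            for c in included_cases:
                score, model = clf.validate_image_wise(
                    c,
                    train_fraction=config.train_fraction,
                    ridge=config.ridge,
                    seed=int(split_rng.integers(2**31)),
                )
                scores.append(score)
                if overlays_done < config.n_overlays and np.isfinite(score.intensity_threshold):
                    clf.render_overlay(
                        c,
                        model,
                        score.intensity_threshold,
                        overlay_path=classify_dir / f"{c.image_id}_overlay.png",
                        suppressed_path=classify_dir / f"{c.image_id}_suppressed.tif",
                    )
                    overlays_done += 1
        if "loocv" in config.schemes:
            for cohort in ("EPR", "ANGIO"):
                cohort_cases = [c for c in included_cases if c.patient.cohort == cohort]
                if len(cohort_cases) < 2:
                    warnings.warn(f"cohort {cohort}: <2 cases, leave-one-out skipped")
                    continue
                loo_scores, _ = clf.validate_loocv(cohort_cases, ridge=config.ridge)
                scores.extend(loo_scores)

        score_df = pd.DataFrame([dataclasses.asdict(s) for s in scores])
        score_df.to_csv(classify_dir / "validation_scores.csv", index=False, float_format="%.10g")
        classification: dict = {"mean_scores": {}}
        for scheme in config.schemes:
            for cohort in ("EPR", "ANGIO"):
                sub = score_df[(score_df["scheme"] == scheme) & (score_df["cohort"] == cohort)] if len(score_df) else score_df
                if len(sub) == 0:
                    continue
                classification["mean_scores"][f"{scheme}/{cohort}"] = {
                    "n_images": int(len(sub)),
                    "mean_auc": float(sub["auc"].mean()),
                    "mean_sensitivity": float(sub["sensitivity"].mean()),
                    "mean_specificity": float(sub["specificity"].mean()),
                }
        report["classification"] = classification
    except Exception as exc:
        raise RuntimeError(f"classification stage failed: {exc}") from exc

    write_report(report, out / "report")
    return report


def _plot_histogram(tumor: np.ndarray, healthy: np.ndarray, cohort: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    edges = np.histogram_bin_edges(np.concatenate([tumor, healthy]), bins=50)
    ax.hist(healthy, bins=edges, alpha=0.6, label="healthy", color="tab:orange")
    ax.hist(tumor, bins=edges, alpha=0.6, label="tumor", color="tab:blue")
    ax.set_xlabel("pixel intensity (counts)")
    ax.set_ylabel("pixel count")
    ax.set_title(f"{cohort} cohort pooled pixel intensities")
    ax.legend()
    fig.tight_layout()
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.4g}"
    return str(x)


def write_report(report: dict, out_dir) -> tuple[Path, Path]:
    """Serialize the report as JSON plus a human-readable Markdown digest.

    Every number printed in the Markdown is drawn from the JSON dict, so the
    two artifacts can never disagree.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    lines = [
        "# Fluorescence-guided surgery TBR run report",
        "",
        f"- config hash: `{report['config_hash']}`",
        f"- seed: {report['config']['seed']}",
        "",
        "## Exclusions",
        "",
        "| reason | n |",
        "| --- | --- |",
    ]
    for reason, n in report.get("exclusions", {}).items():
        lines.append(f"| {reason} | {n} |")

    tbr_block = report.get("tbr", {})
    lines += ["", "## TBR summary", ""]
    if tbr_block.get("skipped"):
        lines.append(f"Cohort comparison skipped: {tbr_block.get('reason', '')}")
    else:
        lines += ["| stratum | n | mean | SD | vs | p (two-sided) |", "| --- | --- | --- | --- | --- | --- |"]
        for s in tbr_block.get("summaries", []):
            lines.append(
                "| {stratum} | {n} | {mean} | {sd} | {vs} | {p} |".format(
                    stratum=s["stratum"],
                    n=s["n_images"],
                    mean=_fmt(s["tbr_mean"]),
                    sd=_fmt(s["tbr_sd"]) if s["tbr_sd"] is not None else "--",
                    vs=s["compared_to"] or "--",
                    p=_fmt(s["p_two_sided"]) if s["p_two_sided"] is not None else "--",
                )
            )
        above = tbr_block.get("cohorts_above_detectability", {})
        ref = tbr_block.get("detectability_reference")
        if above:
            lines += [
                "",
                f"Cohort means vs the TBR > {_fmt(ref)} clinical-detectability reference: "
                + ", ".join(f"{k}: {'above' if v else 'below'}" for k, v in sorted(above.items())),
            ]

    pix = report.get("pixel_tests", {})
    if pix.get("per_cohort"):
        lines += ["", "## Pooled pixel-intensity tests (tumor > healthy)", "", "| cohort | n tumor px | n healthy px | z | p (one-sided) |", "| --- | --- | --- | --- | --- |"]
        for cohort, d in sorted(pix["per_cohort"].items()):
            lines.append(
                f"| {cohort} | {d['n_tumor_px']} | {d['n_healthy_px']} | {_fmt(d['z_value'])} | {_fmt(d['p_one_sided_greater'])} |"
            )

    cls_block = report.get("classification", {}).get("mean_scores", {})
    if cls_block:
        lines += ["", "## Classifier validation", "", "| scheme/cohort | n | mean AUC | mean sens | mean spec |", "| --- | --- | --- | --- | --- |"]
        for key, d in sorted(cls_block.items()):
            lines.append(
                f"| {key} | {d['n_images']} | {_fmt(d['mean_auc'])} | {_fmt(d['mean_sensitivity'])} | {_fmt(d['mean_specificity'])} |"
            )

    md_path = out_dir / "report.md"
    md_path.write_text("\n".join(lines) + "\n")
    return json_path, md_path
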