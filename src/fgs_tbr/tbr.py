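"""Tumor-to-background ratio (TBR) quantification and cohort comparison.

TBR is the mean fluorescence intensity over the tumor ground-truth region
divided by the mean over the healthy region.  Whole-specimen (ex vivo)
images of tumors buried deeper than 4 mm are excluded — beyond the depth
penetration limit of ICG fluorescence the surface signal no longer reflects
the tumor — while grossed sections expose the tumor at the cut surface and
are never depth-excluded.  Included TBRs are summarized per cohort
(angiography vs EPR injection timing) and per subgroup (age, BMI,
histological subtype, receptor status, tumor depth), with unpaired rank-sum
tests between paired strata.

``TBRCohortModel`` / ``TBRCohortResults`` present the cohort analysis in the
model-object idiom: build from a results table, ``fit()``, ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import FluorescenceImage, PatientRecord, RegionMask, extract_pixel_samples
from .exceptions import DataIntegrityError, UndefinedRatioError
from .stats import RankSumResult, rank_sum_test

logger = logging.getLogger(__name__)

__all__ = [
    "TBRResult",
    "CohortSummary",
    "compute_tbr",
    "apply_exclusions",
    "summarize_cohorts",
    "pixel_level_comparison",
    "TBRCohortModel",
    "TBRCohortResults",
]

EXCLUSION_REASONS = ("none", "depth_gt_4mm", "technical", "no_tumor_identified", "no_tumor_present")

DEPTH_CUT_MM = 4.0
AGE_CUT_YEARS = 60.0
BMI_CUT = 25.0


@dataclass
class TBRResult:
    """Per-image TBR with inclusion/exclusion status."""

    image_id: str
    patient_id: str
    tbr: float
    tumor_mean: float
    healthy_mean: float
    n_tumor_px: int
    n_healthy_px: int
    acquisition_context: str = "ex_vivo_whole"
    included: bool = True
    exclusion_reason: str = "none"


@dataclass
class CohortSummary:
    """Mean +/- SD of included TBRs in one stratum, with the rank-sum
    comparison against its paired stratum when one exists."""

    label: str
    n_images: int
    tbr_mean: float
    tbr_sd: float
    compared_to: str | None = None
    comparison: RankSumResult | None = None
    p_adjusted: float | None = None


def compute_tbr(
    image: FluorescenceImage,
    mask: RegionMask,
    image_id: str = "",
    patient_id: str = "",
) -> TBRResult:
    """TBR = mean tumor intensity / mean healthy intensity for one image."""
    tumor, healthy = extract_pixel_samples(image, mask)
    tumor_mean = float(tumor.mean())
    healthy_mean = float(healthy.mean())
    if healthy_mean == 0.0:
        raise UndefinedRatioError("healthy-region mean intensity is zero; TBR undefined")
    return TBRResult(
        image_id=image_id,
        patient_id=patient_id,
        tbr=tumor_mean / healthy_mean,
        tumor_mean=tumor_mean,
        healthy_mean=healthy_mean,
        n_tumor_px=int(tumor.size),
        n_healthy_px=int(healthy.size),
        acquisition_context=image.acquisition_context,
    )


def apply_exclusions(
    results: Sequence[TBRResult],
    patients: Mapping[str, PatientRecord],
    depth_cut_mm: float = DEPTH_CUT_MM,
) -> list[TBRResult]:
    """Apply the depth-penetration exclusion rule; never alters TBR values.

    Whole-specimen (``ex_vivo_whole``) images with invasive tumor depth
    strictly greater than ``depth_cut_mm`` are flagged ``depth_gt_4mm``;
    grossed-section images are never depth-excluded.  Pre-existing exclusion
    flags (technical failures, unidentifiable or absent tumor) pass through
    untouched.  Every result must join to a patient record.
    """
    out: list[TBRResult] = []
    for res in results:
        if res.patient_id not in patients:
            raise DataIntegrityError(f"result {res.image_id!r} joins to no patient record")
        new = replace(res)
        if new.exclusion_reason == "none":
            depth = patients[res.patient_id].tumor_depth_mm
            if (
                new.acquisition_context == "ex_vivo_whole"
                and np.isfinite(depth)
                and depth > depth_cut_mm
            ):
                new.included = False
                new.exclusion_reason = "depth_gt_4mm"
        else:
            new.included = False
        out.append(new)
    return out


def _summary_stats(values: np.ndarray) -> tuple[float, float]:
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else float("nan")
    return mean, sd


def _pairwise(levels: list[str]) -> list[tuple[str, str]]:
    return [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]


def summarize_cohorts(
    results: Sequence[TBRResult],
    patients: Mapping[str, PatientRecord],
    stratifiers: Sequence[str] = ("age", "bmi", "subtype", "receptor_status", "depth"),
    age_cut: float = AGE_CUT_YEARS,
    bmi_cut: float = BMI_CUT,
    depth_cut_mm: float = DEPTH_CUT_MM,
    holm: bool = False,
) -> list[CohortSummary]:
    """Cohort and subgroup TBR summaries with rank-sum comparisons.

    Uses only included results.  Emits one summary per non-empty stratum:
    the whole dataset, each cohort (EPR vs ANGIO compared head-to-head), and
    within each cohort every requested stratifier (age dichotomized at 60
    years, BMI at 25 kg/m2, depth at the 4 mm penetration cut, categorical
    stratifiers compared pairwise).  ``holm`` applies a Holm step-down
    adjustment across all comparisons.
    """
    model = TBRCohortModel.from_results(results, patients)
    fitted = model.fit(
        stratifiers=stratifiers,
        age_cut=age_cut,
        bmi_cut=bmi_cut,
        depth_cut_mm=depth_cut_mm,
        holm=holm,
    )
    return fitted.summaries


def pixel_level_comparison(tumor_pixels, healthy_pixels) -> RankSumResult:
    """One-sided (tumor greater) rank-sum test on pixel intensities.

    Used both per image and at cohort level, where the caller pools all
    tumor and all healthy pixels across the cohort's images first.
    """
    return rank_sum_test(tumor_pixels, healthy_pixels, alternative="greater")


# ---------------------------------------------------------------------------
# model-object surface


class TBRCohortModel:
    """Cohort TBR analysis built from a per-image results table.

    The table needs columns ``tbr``, ``cohort`` and ``included`` plus any
    stratifier columns (``age_years``, ``bmi``, ``subtype``,
    ``receptor_status``, ``tumor_depth_mm``).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"tbr", "cohort", "included"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"results table missing columns {sorted(missing)}")
        self.table = table.reset_index(drop=True)

    @classmethod
    def from_results(
        cls, results: Sequence[TBRResult], patients: Mapping[str, PatientRecord]
    ) -> "TBRCohortModel":
        rows = []
        for res in results:
            if res.patient_id not in patients:
                raise DataIntegrityError(f"result {res.image_id!r} joins to no patient record")
            p = patients[res.patient_id]
            rows.append(
                {
                    "image_id": res.image_id,
                    "patient_id": res.patient_id,
                    "tbr": res.tbr,
                    "included": res.included,
                    "cohort": p.cohort,
                    "age_years": p.age_years,
                    "bmi": p.bmi,
                    "subtype": p.subtype,
                    "receptor_status": p.receptor_status,
                    "tumor_depth_mm": p.tumor_depth_mm,
                }
            )
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TBRCohortModel":
        df = df.copy()
        if "included" not in df.columns:
            df["included"] = True
        return cls(df)

    def fit(
        self,
        stratifiers: Sequence[str] = ("age", "bmi", "subtype", "receptor_status", "depth"),
        age_cut: float = AGE_CUT_YEARS,
        bmi_cut: float = BMI_CUT,
        depth_cut_mm: float = DEPTH_CUT_MM,
        holm: bool = False,
    ) -> "TBRCohortResults":
        df = self.table[self.table["included"]].copy()
        summaries: list[CohortSummary] = []
        groups: dict[str, np.ndarray] = {}

        def add(label: str, values: np.ndarray):
            if values.size == 0:
                logger.warning("stratum %r is empty; skipped", label)
                return
            mean, sd = _summary_stats(values)
            summaries.append(CohortSummary(label, int(values.size), mean, sd))
            groups[label] = values

        add("all", df["tbr"].to_numpy())
        for cohort in ("EPR", "ANGIO"):
            add(cohort, df.loc[df["cohort"] == cohort, "tbr"].to_numpy())

        pairs: list[tuple[str, str]] = []
        if "EPR" in groups and "ANGIO" in groups:
            pairs.append(("ANGIO", "EPR"))

        def dichotomy(col: str, cut: float, name: str, sub: pd.DataFrame, prefix: str):
            vals = sub[col].to_numpy(dtype=float)
            lo = sub.loc[vals < cut, "tbr"].to_numpy()
            hi = sub.loc[vals >= cut, "tbr"].to_numpy()
            la, lb = f"{prefix}{name}<{cut:g}", f"{prefix}{name}>={cut:g}"
            add(la, lo)
            add(lb, hi)
            if la in groups and lb in groups:
                pairs.append((la, lb))

        for cohort in ("EPR", "ANGIO"):
            sub = df[df["cohort"] == cohort]
            if sub.empty:
                continue
            prefix = f"{cohort}/"
            for strat in stratifiers:
                if strat == "age" and "age_years" in sub:
                    dichotomy("age_years", age_cut, "age", sub, prefix)
                elif strat == "bmi" and "bmi" in sub:
                    dichotomy("bmi", bmi_cut, "bmi", sub, prefix)
                elif strat == "depth" and "tumor_depth_mm" in sub:
                    dichotomy("tumor_depth_mm", depth_cut_mm, "depth", sub, prefix)
                elif strat in ("subtype", "receptor_status") and strat in sub:
                    levels = sorted(sub[strat].dropna().unique().tolist())
                    for lev in levels:
                        add(f"{prefix}{strat}={lev}", sub.loc[sub[strat] == lev, "tbr"].to_numpy())
                    for la, lb in _pairwise(levels):
                        ka, kb = f"{prefix}{strat}={la}", f"{prefix}{strat}={lb}"
                        if ka in groups and kb in groups:
                            pairs.append((ka, kb))

        comparisons: list[tuple[str, str, RankSumResult]] = []
        for la, lb in pairs:
            comparisons.append((la, lb, rank_sum_test(groups[la], groups[lb])))

        p_adj: list[float] | None = None
        if holm and comparisons:
            from statsmodels.stats.multitest import multipletests

            p_adj = multipletests([c[2].p_two_sided for c in comparisons], method="holm")[1].tolist()

        by_label = {s.label: s for s in summaries}
        for k, (la, lb, res) in enumerate(comparisons):
            for here, there in ((la, lb), (lb, la)):
                s = by_label.get(here)
                if s is not None and s.comparison is None:
                    s.compared_to = there
                    s.comparison = res
                    if p_adj is not None:
                        s.p_adjusted = float(p_adj[k])

        return TBRCohortResults(self, summaries, comparisons, p_adj)


class TBRCohortResults:
    """Fitted cohort analysis: stratum summaries and pairwise comparisons."""

    def __init__(
        self,
        model: TBRCohortModel,
        summaries: list[CohortSummary],
        comparisons: list[tuple[str, str, RankSumResult]],
        p_adjusted: list[float] | None = None,
    ):
        self.model = model
        self.summaries = summaries
        self.comparisons = comparisons
        self.p_adjusted = p_adjusted

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.summaries:
            rows.append(
                {
                    "stratum": s.label,
                    "n_images": s.n_images,
                    "tbr_mean": s.tbr_mean,
                    "tbr_sd": s.tbr_sd,
                    "compared_to": s.compared_to or "",
                    "p_two_sided": s.comparison.p_two_sided if s.comparison else float("nan"),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "TBR cohort analysis",
            "=" * 74,
            f"{'stratum':<28}{'n':>5}{'mean':>9}{'SD':>9}{'vs':>14}{'p':>9}",
            "-" * 74,
        ]
        for s in self.summaries:
            p = f"{s.comparison.p_two_sided:.4f}" if s.comparison else ""
            sd = f"{s.tbr_sd:.2f}" if np.isfinite(s.tbr_sd) else "--"
            lines.append(
                f"{s.label:<28}{s.n_images:>5}{s.tbr_mean:>9.2f}{sd:>9}"
                f"{(s.compared_to or ''):>14}{p:>9}"
            )
        lines.append("-" * 74)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "summaries": [
                {
                    "stratum": s.label,
                    "n_images": s.n_images,
                    "tbr_mean": s.tbr_mean,
                    "tbr_sd": None if not np.isfinite(s.tbr_sd) else s.tbr_sd,
                    "compared_to": s.compared_to,
                    "p_two_sided": s.comparison.p_two_sided if s.comparison else None,
                    "p_adjusted": s.p_adjusted,
                }
                for s in self.summaries
            ],
            "comparisons": [
                {
                    "a": la,
                    "b": lb,
                    "u_statistic": r.u_statistic,
                    "z_value": r.z_value,
                    "p_two_sided": r.p_two_sided,
                    "method": r.method,
                }
                for la, lb, r in self.comparisons
            ],
        }
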