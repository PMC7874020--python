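"""Model/results objects — the package's top-level API.

Two fitted-model pairs cover the analysis:

* :class:`NegativeNetworkModel` — one patient's scan.  Built from a 4-D
  BOLD image, an epileptogenic-zone seed mask and a brain mask; ``fit()``
  preprocesses (smooth, grand-mean scale), maps voxel-wise seed
  correlation, thresholds the negatively (and optionally positively)
  correlated network, and summarises each as intraconnectivity + spread.
  The returned :class:`NetworkResults` can additionally score the same
  voxel set on a post-operative scan or rerun the whole procedure from a
  random control seed.

* :class:`CohortOutcomeModel` — the cohort table.  ``fit()`` runs the
  statistics battery: seizure-free vs not group comparisons, Spearman
  correlations against neuropsychological scores with Bonferroni
  control, demographics, and the ROC prognosis of seizure freedom from
  network connectivity.

Both results objects expose ``summary()`` returning a printable report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import io as _io
from .images import Bold4D, CorrelationMap, VoxelMask, check_same_geometry
from .mapping import (
    NEGATIVE_THRESHOLD_DEFAULT,
    NetworkDefinition,
    correlation_map,
    extract_seed_timeseries,
    random_control_roi,
    threshold_network,
)
from .metrics import NetworkMetrics, compute_network_metrics, postop_connectivity
from .preprocess import gaussian_smooth, grand_mean_scale
from .stats import (
    RocResult,
    TestResult,
    demographics_summary,
    roc_analysis,
    spearman_with_bonferroni,
    two_sample_ttest,
)

__all__ = ["NegativeNetworkModel", "NetworkResults", "CohortOutcomeModel", "CohortResults"]


class NegativeNetworkModel:
    """Seed-based anticorrelated-network model for a single patient.

    Parameters
    ----------
    bold : Bold4D
        Pre-operative resting-state scan (assumed motion-corrected and
        co-registered; no registration is performed here).
    seed : VoxelMask
        Hypothesized epileptogenic-zone seed.
    brain : VoxelMask
        Brain mask restricting the correlation map.
    negative_threshold : float
        Cut for the negatively correlated network (r strictly below);
        default -0.4.
    smooth_fwhm_mm : float or None
        Isotropic-in-mm Gaussian FWHM applied before mapping (default
        8 mm); None skips smoothing.
    grand_mean_target : float or None
        Grand-mean scaling target (default 100); None skips scaling.
    run_positive_network : bool
        Also derive the positively correlated network, thresholded at
        the patient's mean correlation.
    """

    def __init__(
        self,
        bold: Bold4D,
        seed: VoxelMask,
        brain: VoxelMask,
        *,
        negative_threshold: float = NEGATIVE_THRESHOLD_DEFAULT,
        smooth_fwhm_mm: Optional[float] = 8.0,
        grand_mean_target: Optional[float] = 100.0,
        run_positive_network: bool = True,
    ):
        check_same_geometry(bold, brain, "bold vs brain")
        check_same_geometry(bold, seed, "bold vs seed")
        if seed.n_voxels < 1:
            raise ValueError("seed mask is empty")
        if not negative_threshold < 0:
            raise ValueError("negative_threshold must be < 0")
        self.bold = bold
        self.seed = seed
        self.brain = brain
        self.negative_threshold = float(negative_threshold)
        self.smooth_fwhm_mm = smooth_fwhm_mm
        self.grand_mean_target = grand_mean_target
        self.run_positive_network = run_positive_network

    @classmethod
    def from_files(cls, bold_path, seed_path, brain_path, **kwargs) -> "NegativeNetworkModel":
        return cls(
            _io.load_bold(bold_path),
            _io.load_mask(seed_path, "seed"),
            _io.load_mask(brain_path, "brain"),
            **kwargs,
        )

    def _preprocess(self, img: Bold4D) -> Bold4D:
        if self.smooth_fwhm_mm is not None:
            img = gaussian_smooth(img, self.smooth_fwhm_mm)
        if self.grand_mean_target is not None:
            img = grand_mean_scale(img, self.brain, self.grand_mean_target)
        return img

    def fit(self) -> "NetworkResults":
        img = self._preprocess(self.bold)
        seed_ts = extract_seed_timeseries(img, self.seed)
        cmap = correlation_map(img, seed_ts, self.brain)
        negative = threshold_network(cmap, "negative", self.negative_threshold, self.seed)
        networks = {"negative": negative}
        if self.run_positive_network:
            networks["positive"] = threshold_network(cmap, "positive", None, self.seed)
        metrics = {
            name: compute_network_metrics(img, net, self.seed)
            for name, net in networks.items()
        }
        return NetworkResults(
            model=self,
            preprocessed=img,
            seed_timeseries=seed_ts,
            correlation_map=cmap,
            networks=networks,
            metrics=metrics,
        )


@dataclass
class NetworkResults:
    """Fitted per-patient network analysis."""

    model: NegativeNetworkModel
    preprocessed: Bold4D
    seed_timeseries: np.ndarray
    correlation_map: CorrelationMap
    networks: dict[str, NetworkDefinition]
    metrics: dict[str, NetworkMetrics]

    @property
    def negative_network(self) -> NetworkDefinition:
        return self.networks["negative"]

    @property
    def intraconnectivity(self) -> Optional[float]:
        return self.metrics["negative"].intraconnectivity

    @property
    def spread_mm(self) -> Optional[float]:
        return self.metrics["negative"].spread_mm

    def postop(self, postop_bold: Bold4D) -> tuple[Optional[float], int]:
        """Connectivity of the pre-operative negative-network voxel set
        on a post-operative scan (same preprocessing applied).  Returns
        ``(value, n_excluded_zero_variance)``."""
        check_same_geometry(postop_bold, self.model.brain, "postop vs brain")
        img = self.model._preprocess(postop_bold)
        return postop_connectivity(img, self.negative_network)

    def control_analysis(
        self, region: VoxelMask, n_voxels: int = 907, rng_seed: int = 0
    ) -> "NetworkResults":
        """Re-run the full analysis seeded from a contiguous random ROI
        of ``n_voxels`` voxels inside ``region`` (occipital in the
        reference analysis; size matched to the average EZ seed)."""
        roi = random_control_roi(self.model.brain, region, n_voxels, rng_seed)
        ctrl = NegativeNetworkModel(
            self.model.bold, roi, self.model.brain,
            negative_threshold=self.model.negative_threshold,
            smooth_fwhm_mm=self.model.smooth_fwhm_mm,
            grand_mean_target=self.model.grand_mean_target,
            run_positive_network=self.model.run_positive_network,
        )
        return ctrl.fit()

    def to_dict(self) -> dict:
        return {
            "parameters": {
                "negative_threshold": self.model.negative_threshold,
                "smooth_fwhm_mm": self.model.smooth_fwhm_mm,
                "grand_mean_target": self.model.grand_mean_target,
            },
            "n_zero_variance_voxels": self.correlation_map.n_zero_variance,
            "networks": {name: m.to_dict() for name, m in self.metrics.items()},
        }

    def summary(self) -> str:
        lines = [
            "Negatively correlated epilepsy network — patient summary",
            "=" * 58,
            f"seed voxels:            {self.model.seed.n_voxels}",
            f"brain voxels:           {self.model.brain.n_voxels}",
            f"zero-variance excluded: {self.correlation_map.n_zero_variance}",
            "",
            f"{'network':<10}{'thresh':>8}{'voxels':>8}{'intraconn':>11}{'spread_mm':>11}",
        ]
        for name, m in self.metrics.items():
            ic = "NA" if m.intraconnectivity is None else f"{m.intraconnectivity:.4f}"
            sp = "NA" if m.spread_mm is None else f"{m.spread_mm:.1f}"
            lines.append(f"{name:<10}{m.threshold:>8.3f}{m.n_voxels:>8}{ic:>11}{sp:>11}")
        return "\n".join(lines)


class CohortOutcomeModel:
    """Cohort-level statistics over per-patient network metrics.

    Parameters
    ----------
    table : DataFrame
        One row per patient; needs ``seizure_free`` plus whichever of
        ``intraconnectivity`` / ``spread_mm`` / neuropsych columns the
        requested analyses use.
    score : str
        Prognostic column for group tests and ROC (default
        ``intraconnectivity``).
    neuropsych_columns : list of str, optional
        Columns to correlate against ``score`` with Spearman rho.
    family_size : int, optional
        Bonferroni family size; defaults to the number of neuropsych
        columns actually tested.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        *,
        score: str = "intraconnectivity",
        outcome: str = "seizure_free",
        neuropsych_columns: Optional[list[str]] = None,
        family_size: Optional[int] = None,
    ):
        if len(table) < 1:
            raise ValueError("cohort table is empty")
        if table["id"].duplicated().any() if "id" in table.columns else False:
            raise ValueError("cohort table ids must be unique")
        self.table = table.reset_index(drop=True)
        self.score = score
        self.outcome = outcome
        self.neuropsych_columns = neuropsych_columns or []
        self.family_size = family_size

    @classmethod
    def from_file(cls, path, **kwargs) -> "CohortOutcomeModel":
        return cls(_io.load_cohort_table(path), **kwargs)

    def fit(self) -> "CohortResults":
        t = self.table
        demo = demographics_summary(t)
        ttest = roc = None
        if self.outcome in t.columns and self.score in t.columns:
            out = t[self.outcome].astype(bool)
            scores = pd.to_numeric(t[self.score], errors="coerce")
            groups = (scores[out].dropna(), scores[~out].dropna())
            if len(groups[0]) >= 2 and len(groups[1]) >= 2:
                ttest = two_sample_ttest(groups[0], groups[1], name=self.score)
            if out.any() and (~out).any() and scores.notna().any():
                roc = roc_analysis(scores, out)
        spearman = []
        if self.neuropsych_columns:
            spearman = spearman_with_bonferroni(
                t, self.score, self.neuropsych_columns, self.family_size
            )
        return CohortResults(
            model=self, demographics=demo, group_test=ttest,
            roc=roc, spearman=spearman,
        )


@dataclass
class CohortResults:
    """Fitted cohort analysis: demographics, group test, ROC, correlations."""

    model: CohortOutcomeModel
    demographics: dict
    group_test: Optional[TestResult]
    roc: Optional[RocResult]
    spearman: list[TestResult]

    def to_dict(self) -> dict:
        out: dict = {"demographics": self.demographics}
        if self.group_test is not None:
            g = self.group_test
            out["group_comparison"] = {
                "statistic": g.statistic, "p_value": g.p_value,
                "n_seizure_free": g.n1, "n_not_free": g.n2,
                "mean_difference": g.estimate,
            }
        if self.roc is not None:
            out["roc"] = {
                "auc": self.roc.auc, "ci95": list(self.roc.ci95),
                "selected_thresholds": self.roc.selected,
                "n_positive": self.roc.n_positive,
                "n_negative": self.roc.n_negative,
            }
        if self.spearman:
            out["spearman"] = [
                {
                    "column": r.name, "rho": r.estimate, "p_value": r.p_value,
                    "adjusted_p": r.adjusted_p, "n": r.n1, "computable": r.computable,
                }
                for r in self.spearman
            ]
        return out

    def summary(self) -> str:
        lines = ["Cohort outcome analysis", "=" * 58]
        d = self.demographics
        lines.append(f"patients: {d.get('n_patients')}")
        if "seizure_free" in d:
            sf = d["seizure_free"]
            for key in ("Yes", "No"):
                if key in sf:
                    lines.append(
                        f"  seizure free = {key}: {sf[key]['count']} ({sf[key]['percent']}%)"
                    )
        if self.group_test is not None:
            g = self.group_test
            lines += [
                "",
                f"{self.model.score} by outcome (pooled t-test):",
                f"  t = {g.statistic:.4f}, p = {g.p_value:.4g} "
                f"(n = {g.n1}/{g.n2}, mean diff = {g.estimate:.4f})",
            ]
        if self.roc is not None:
            r = self.roc
            lines += [
                "",
                f"ROC (higher {self.model.score} => predicts seizure freedom):",
                f"  AUC = {r.auc:.3f} (95% CI {r.ci95[0]:.3f}-{r.ci95[1]:.3f})",
                "  thresholds: " + ", ".join(
                    f"{label} = {val:.4f}" if val is not None else f"{label} = NA"
                    for label, val in (
                        ("youden", r.selected["youden"]),
                        ("max sens", r.selected["max_sensitivity"]),
                        ("max spec", r.selected["max_specificity"]),
                    )
                ),
            ]
        if self.spearman:
            lines += ["", f"Spearman rho vs {self.model.score} (Bonferroni-adjusted):"]
            for s in self.spearman:
                if not s.computable:
                    lines.append(f"  {s.name:<12} not computable (n = {s.n1})")
                else:
                    lines.append(
                        f"  {s.name:<12} rho = {s.estimate:+.3f}, p = {s.p_value:.4g}, "
                        f"adj p = {s.adjusted_p:.4g} (n = {s.n1})"
                    )
        return "\n".join(lines)
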