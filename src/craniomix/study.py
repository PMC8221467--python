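"""Study orchestration: the `AncestryStudy` model and its fitted results.

`AncestryStudy` wraps a landmark dataset plus the study design (symmetry
scheme, source/target groups, posterior threshold); `fit()` runs, per sex,
the full chain — joint GPA with reflected copies, symmetric-component
extraction, PCA, four-group CVA, stepwise cross-validated PC reduction,
overall and pairwise Wilks MANOVAs, two-source LDA and posterior-threshold
attribution of each target group — and optionally the mixed-sex pooled
variant.  The mean-posterior ("admixture") estimates are part of every
attribution summary.  The whole fit is deterministic: leave-one-out
cross-validation is the only resampling and involves no randomness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ancestry import AttributionReport, LDAModel, attribute_individuals, fit_lda, summarize
from .group_stats import (
    PCReductionResult,
    WilksResult,
    baylac_friess_reduce,
    pairwise_manova,
    wilks_manova,
)
from .io import Group, ShapeDataset
from .ordination import CVAResult, PCAResult, cva, pca
from .symmetry import SymmetryScheme, symmetrize

logger = logging.getLogger("craniomix")


@dataclass
class StudyConfig:
    """Design parameters of one attribution study."""

    source_groups: tuple = (Group.DANISH.value, Group.PREMED_BRITISH.value)
    target_groups: tuple = (Group.EARLY_AS.value, Group.MIDDLE_AS.value)
    threshold: float = 0.55
    sexes: tuple = ("F", "M")
    mixed_sex: bool = True
    priors: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        self.source_groups = tuple(str(getattr(g, "value", g)) for g in self.source_groups)
        self.target_groups = tuple(str(getattr(g, "value", g)) for g in self.target_groups)
        if len(self.source_groups) != 2:
            raise ValueError("exactly two source groups are required")
        if not 0.5 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0.5, 1)")


@dataclass
class SexAnalysis:
    """All fitted objects for one sex stratum (or the pooled mixed-sex run)."""

    label: str  # "F", "M" or "mixed"
    n: int
    symmetrized: ShapeDataset
    pca: PCAResult
    cva: CVAResult
    reduction: PCReductionResult
    overall_manova: WilksResult
    pairwise: list[WilksResult]
    pair_names: list[tuple[str, str]]
    lda: LDAModel
    attributions: dict[str, AttributionReport] = field(default_factory=dict)


class AncestryStudy:
    """Model object: a landmark dataset plus the study design, ready to fit."""

    def __init__(
        self,
        dataset: ShapeDataset,
        scheme: SymmetryScheme | None = None,
        config: StudyConfig | None = None,
    ) -> None:
        self.dataset = dataset
        self.scheme = scheme or dataset.scheme
        if self.scheme is None:
            raise ValueError("a SymmetryScheme is required (dataset carries none)")
        self.config = config or StudyConfig()
        dataset._require_metadata()

    @classmethod
    def from_files(
        cls,
        path,
        dialect="CSV",
        metadata_path=None,
        scheme_path=None,
        config: StudyConfig | None = None,
        layout: str = "wide",
    ) -> "AncestryStudy":
        from .io import read_landmarks

        ds = read_landmarks(path, dialect=dialect, metadata_path=metadata_path, layout=layout)
        scheme = SymmetryScheme.from_yaml(scheme_path) if scheme_path else SymmetryScheme.default(ds.k)
        return cls(ds, scheme=scheme, config=config)

    # ------------------------------------------------------------------

    def _fit_stratum(self, data: ShapeDataset, label: str) -> SexAnalysis:
        cfg = self.config
        logger.info("stratum %s: n=%d specimens, k=%d landmarks", label, len(data), data.k)
        sym = symmetrize(data, self.scheme)
        groups = sym.groups()
        pca_res = pca(sym)
        cva_res = cva(sym.coords_array().reshape(len(sym), -1), groups)
        red = baylac_friess_reduce(pca_res, groups)
        X = pca_res.scores[:, red.retained_indices]
        overall = wilks_manova(X, groups)
        order = list(dict.fromkeys(list(cfg.source_groups) + list(cfg.target_groups)))
        present = [g for g in order if (groups == g).any()]
        pairs = [
            (present[i], present[j])
            for i in range(len(present))
            for j in range(i + 1, len(present))
        ]
        pw = pairwise_manova(X, groups, pairs)
        src_mask = np.isin(groups, cfg.source_groups)
        lda = fit_lda(X[src_mask], groups[src_mask], classes=cfg.source_groups, priors=cfg.priors)
        ids = np.array(sym.specimen_ids())
        attributions = {}
        for tg in cfg.target_groups:
            mask = groups == tg
            if not mask.any():
                continue
            indiv = attribute_individuals(lda, X[mask], ids[mask], threshold=cfg.threshold)
            attributions[tg] = summarize(indiv, target_group=tg)
        logger.info(
            "stratum %s: %d PCs retained (%.0f%% variance), lambda=%.3f, source LOOCV=%.2f",
            label,
            red.n_retained,
            100 * red.retained_variance_fraction,
            overall.lambda_,
            lda.loocv_accuracy,
        )
        return SexAnalysis(
            label=label,
            n=len(data),
            symmetrized=sym,
            pca=pca_res,
            cva=cva_res,
            reduction=red,
            overall_manova=overall,
            pairwise=pw,
            pair_names=pairs,
            lda=lda,
            attributions=attributions,
        )

    def fit(self) -> "AncestryStudyResults":
        """Run the full per-sex chain (and the pooled variant when configured)."""
        cfg = self.config
        per_sex: dict[str, SexAnalysis] = {}
        for sex in cfg.sexes:
            data = self.dataset.subset(sex=sex)
            per_sex[sex] = self._fit_stratum(data, sex)
        mixed = self._fit_stratum(self.dataset, "mixed") if cfg.mixed_sex else None
        return AncestryStudyResults(model=self, per_sex=per_sex, mixed=mixed)


class AncestryStudyResults:
    """Fitted estimates, test statistics and attribution tables with exporters."""

    def __init__(self, model: AncestryStudy, per_sex: dict, mixed: SexAnalysis | None):
        self.model = model
        self.per_sex = per_sex
        self.mixed = mixed

    def _strata(self):
        out = dict(self.per_sex)
        if self.mixed is not None:
            out["mixed"] = self.mixed
        return out

    # ------------------------------------------------------------------ tables

    def cva_table(self) -> pd.DataFrame:
        rows = []
        for label, s in self._strata().items():
            for i, frac in enumerate(s.cva.cv_variance_fractions):
                rows.append(
                    {"stratum": label, "cv": i + 1, "variance_pct": 100.0 * frac}
                )
        return pd.DataFrame(rows)

    def manova_table(self) -> pd.DataFrame:
        rows = []
        for label, s in self._strata().items():
            rows.append(
                {
                    "stratum": label,
                    "comparison": "overall",
                    "lambda": s.overall_manova.lambda_,
                    "F": s.overall_manova.F,
                    "df1": s.overall_manova.df1,
                    "df2": s.overall_manova.df2,
                    "p": s.overall_manova.p,
                    "partial_eta_sq": s.overall_manova.partial_eta_sq,
                }
            )
            for (a, b), r in zip(s.pair_names, s.pairwise):
                rows.append(
                    {
                        "stratum": label,
                        "comparison": f"{a} vs {b}",
                        "lambda": r.lambda_,
                        "F": r.F,
                        "df1": r.df1,
                        "df2": r.df2,
                        "p": r.p,
                        "partial_eta_sq": r.partial_eta_sq,
                    }
                )
        return pd.DataFrame(rows)

    def attribution_summary(self) -> pd.DataFrame:
        rows = []
        for label, s in self._strata().items():
            for tg, rep in s.attributions.items():
                rows.append(
                    {
                        "stratum": label,
                        "target_group": tg,
                        "n": rep.n,
                        "pct_danish": rep.pct_danish,
                        "pct_british": rep.pct_british,
                        "pct_unknown": rep.pct_unknown,
                        "mean_posterior_danish": rep.mean_posterior_danish,
                        "mean_posterior_british": rep.mean_posterior_british,
                    }
                )
        return pd.DataFrame(rows)

    def attribution_individuals(self) -> pd.DataFrame:
        frames = []
        for label, s in self._strata().items():
            for tg, rep in s.attributions.items():
                df = rep.to_frame()
                df.insert(0, "stratum", label)
                df.insert(1, "target_group", tg)
                frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def reduction_table(self) -> pd.DataFrame:
        rows = []
        for label, s in self._strata().items():
            rows.append(
                {
                    "stratum": label,
                    "n_retained_pcs": s.reduction.n_retained,
                    "retained_variance_pct": 100.0 * s.reduction.retained_variance_fraction,
                    "peak_loocv_pct": max(p for _, p in s.reduction.cv_curve),
                    "source_loocv_pct": 100.0 * s.lda.loocv_accuracy,
                }
            )
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------ summary

    def summary(self) -> str:
        """Human-readable account of the fitted study."""
        lines = []
        cfg = self.model.config
        lines.append("Craniometric ancestry attribution study")
        lines.append("=" * 55)
        lines.append(
            f"n = {len(self.model.dataset)} specimens, k = {self.model.dataset.k} landmarks; "
            f"threshold = {cfg.threshold:.2f}"
        )
        for label, s in self._strata().items():
            lines.append("")
            lines.append(f"--- stratum: {label} (n = {s.n}) ---")
            cv_pct = ", ".join(
                f"CV{i + 1} {100 * f:.0f}%" for i, f in enumerate(s.cva.cv_variance_fractions)
            )
            lines.append(f"CVA: {s.cva.n_variates} canonical variates ({cv_pct})")
            lines.append(
                f"PC reduction: {s.reduction.n_retained} PCs retained "
                f"({100 * s.reduction.retained_variance_fraction:.0f}% of shape variance)"
            )
            o = s.overall_manova
            lines.append(
                f"overall MANOVA: lambda {o.lambda_:.3f}, F = {o.F:.3f}, "
                f"p = {o.p:.3g}, partial eta^2 = {o.partial_eta_sq:.2f}"
            )
            n_sig = sum(r.p < 0.05 for r in s.pairwise)
            lines.append(f"pairwise MANOVAs: {n_sig}/{len(s.pairwise)} significant at 0.05")
            lines.append(f"source LDA leave-one-out accuracy: {100 * s.lda.loocv_accuracy:.0f}%")
            for tg, rep in s.attributions.items():
                lines.append(
                    f"  {tg}: {rep.pct_danish:.0f}% Danish / {rep.pct_british:.0f}% British / "
                    f"{rep.pct_unknown:.0f}% unattributable  "
                    f"(mean posterior {100 * rep.mean_posterior_danish:.0f}% Danish)"
                )
        return "\n".join(lines)

    # ------------------------------------------------------------------ export

    def to_csv(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = {}
        for name, df in {
            "cva_summary": self.cva_table(),
            "manova_table": self.manova_table(),
            "attribution_summary": self.attribution_summary(),
            "attribution_individuals": self.attribution_individuals(),
            "pc_reduction": self.reduction_table(),
        }.items():
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            written[name] = p
        (outdir / "report.txt").write_text(self.summary() + "\n")
        (outdir / "provenance.yaml").write_text(self._provenance_yaml())
        return written

    def _provenance_yaml(self) -> str:
        import yaml

        from . import __version__

        cfg = self.model.config
        return yaml.safe_dump(
            {
                "package": "craniomix",
                "version": __version__,
                "seed": cfg.seed,
                "threshold": cfg.threshold,
                "source_groups": list(cfg.source_groups),
                "target_groups": list(cfg.target_groups),
                "sexes": list(cfg.sexes),
                "mixed_sex": cfg.mixed_sex,
                "n_specimens": len(self.model.dataset),
                "k_landmarks": self.model.dataset.k,
            }
        )

    # ------------------------------------------------------------------ plots

    def plot_cva(self, stratum: str = "F", axes: tuple[int, int] = (1, 2), ax=None):
        """Scatter of two canonical variates, one marker colour per group."""
        import matplotlib.pyplot as plt

        s = self._strata()[stratum]
        i, j = axes[0] - 1, axes[1] - 1
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        groups = s.symmetrized.groups()
        for g in s.cva.group_labels:
            mask = groups == g
            ax.scatter(s.cva.cv_scores[mask, i], s.cva.cv_scores[mask, j], label=str(g), s=18)
        ax.set_xlabel(f"CV{axes[0]} ({100 * s.cva.cv_variance_fractions[i]:.0f}%)")
        ax.set_ylabel(f"CV{axes[1]} ({100 * s.cva.cv_variance_fractions[j]:.0f}%)")
        ax.set_title(f"Canonical variates, stratum {stratum}")
        ax.legend(fontsize=8)
        return ax

    def save_plots(self, outdir) -> list[Path]:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for label, s in self._strata().items():
            for ax_pair in ((1, 2), (2, 3)):
                if s.cva.n_variates < max(ax_pair):
                    continue
                fig, ax = plt.subplots(figsize=(6, 5))
                self.plot_cva(label, axes=ax_pair, ax=ax)
                p = outdir / f"cva_{label}_cv{ax_pair[0]}x cv{ax_pair[1]}.png".replace(" ", "")
                fig.savefig(p, dpi=120)
                plt.close(fig)
                paths.append(p)
        return paths


def run_study(
    dataset: ShapeDataset,
    scheme: SymmetryScheme | None = None,
    config: StudyConfig | None = None,
) -> AncestryStudyResults:
    """Functional entry point: build the model and fit it."""
    return AncestryStudy(dataset, scheme=scheme, config=config).fit()
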