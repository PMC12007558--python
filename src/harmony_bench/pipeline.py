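"""End-to-end orchestration: simulate/load -> statistics -> harmonise -> report.

``run_all`` executes every stage under one configuration and writes each
artefact as TSV/JSON together with a manifest of content hashes, so two runs
with the same configuration and seed are byte-identical and trivially
diffable.  ``render_report`` turns a completed output directory into a
single markdown document with the benchmark's six figure panels (IQM
heatmaps, the similarity matrix with class distributions, scanner bias, the
three-CoV profile with group aggregation, ranking consistency with its null
band, and the pre/post harmonisation comparison).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import ranking as rk
from . import reliability as rel
from . import similarity as sim
from .harmonise import apply_combat, evaluate_harmonisation, fit_apply_covbat, fit_combat
from .simulate import preset_travelling_heads, simulate_study
from .tables import (
    ContractError,
    StudyData,
    load_study_dir,
    write_study,
    write_table,
)

__all__ = ["RunConfig", "run_all", "render_report"]

log = logging.getLogger("harmony_bench")


@dataclass
class RunConfig:
    """One configuration driving the whole pipeline.

    Either ``preset`` (currently ``"travelling-heads"``) or ``study_dir`` (a
    directory of sessions/idps/idp_categories[/iqms] TSVs) supplies the
    input tables.  The seed governs every stochastic stage (simulation and
    the ranking null).
    """

    out_dir: str
    seed: int
    preset: Optional[str] = "travelling-heads"
    study_dir: Optional[str] = None
    cov_ddof: int = 1
    between_policy: str = "first"
    edge_category: Optional[str] = "fc_edge"
    edge_fraction: float = 0.05
    edge_k: Optional[int] = None
    method: Optional[str] = "combat"  # combat | covbat | None
    covariates: Sequence[str] = ("age", "sex")
    fit_sessions: str = "primary"
    null_draws: int = 10_000
    vendor: Optional[str] = None  # vendor for restricted ranking; default: modal

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ContractError(f"config file {path} did not parse to a mapping")
        if "covariates" in raw and raw["covariates"] is not None:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_input(config: RunConfig) -> tuple[StudyData, Optional[object]]:
    if config.study_dir is not None:
        log.info("loading study from %s", config.study_dir)
        return load_study_dir(config.study_dir), None
    if config.preset != "travelling-heads":
        raise ContractError(f"unknown preset {config.preset!r}")
    spec, cfg = preset_travelling_heads(seed=config.seed)
    study, truth = simulate_study(spec, cfg)
    return study, truth


def _default_vendor(study: StudyData) -> Optional[str]:
    per_vendor = study.sessions.groupby("vendor")["scanner_id"].nunique()
    per_vendor = per_vendor[per_vendor >= 2]
    if per_vendor.empty:
        return None
    return str(per_vendor.idxmax())


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the artefact manifest.

    Artefacts are written stage by stage; if a stage raises, the exception
    carries the stage name and the manifest written so far is still on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "artefacts": {}, "notes": []}

    def _record(name: str, path: Path) -> None:
        manifest["artefacts"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }

    def _flush() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    stage = "load"
    try:
        study, truth = _load_input(config)
        study_dir = out / "study"
        for name, path in write_study(study, study_dir).items():
            _record(f"study/{name}", path)
        if truth is not None:
            gt_path = out / "ground_truth.json"
            with open(gt_path, "w") as fh:
                json.dump(
                    {
                        "gamma": truth.gamma.to_dict(),
                        "delta": truth.delta.to_dict(),
                        "alpha": truth.alpha.to_dict(),
                    },
                    fh,
                    sort_keys=True,
                )
            _record("ground_truth", gt_path)
        log.info("study: %d sessions, %d IDPs", study.n_sessions, study.idps.shape[1])

        stage = "similarity"
        cc = sim.category_correlation_matrices(
            study,
            edge_category=config.edge_category,
            edge_fraction=config.edge_fraction,
            edge_k=config.edge_k,
        )
        P, n_cat = sim.similarity_matrix(cc)
        write_table(P, out / "P.tsv")
        _record("similarity/P", out / "P.tsv")
        for cat, mat in cc.items():
            p = out / "similarity" / f"R_{cat}.tsv"
            write_table(mat, p)
            _record(f"similarity/R_{cat}", p)
        classes = sim.classify_pairs(study.sessions)
        classes.to_csv(out / "pair_classes.tsv", sep="\t", index=False)
        _record("similarity/pair_classes", out / "pair_classes.tsv")
        dist, _ = sim.pair_class_distributions(P, classes)
        write_table(dist, out / "class_distributions.tsv")
        _record("similarity/class_distributions", out / "class_distributions.tsv")

        stage = "reliability"
        report = rel.class_cov_profile(
            study, ddof=config.cov_ddof, between_policy=config.between_policy
        )
        write_table(report.per_idp, out / "reliability_report.tsv")
        _record("reliability/report", out / "reliability_report.tsv")
        for statistic in ("mean", "median"):
            agg = rel.aggregate_by_group(report.per_idp, study.categories, statistic)
            p = out / f"reliability_groups_{statistic}.tsv"
            write_table(agg, p)
            _record(f"reliability/groups_{statistic}", p)
        bias = rel.scanner_bias(study)
        write_table(bias.per_subject, out / "bias_report.tsv")
        _record("reliability/bias", out / "bias_report.tsv")
        write_table(
            pd.DataFrame(
                {"group": bias.group, "group_same_vendor": bias.group_same_vendor}
            ),
            out / "bias_group.tsv",
        )
        _record("reliability/bias_group", out / "bias_group.tsv")
        if config.edge_category is not None:
            edges = rel.select_top_edges(
                study,
                config.edge_category,
                fraction=config.edge_fraction,
                k_override=config.edge_k,
            )
            (out / "retained_edges.txt").write_text("\n".join(edges) + "\n")
            _record("reliability/retained_edges", out / "retained_edges.txt")

        stage = "iqms"
        if study.iqms is not None:
            for ax, name in (
                ("across_scanners", "iqm_z_scanner"),
                ("across_subjects", "iqm_z_subject"),
            ):
                z = rel.zscore_iqms(study, axis=ax)
                write_table(z, out / f"{name}.tsv")
                _record(f"iqms/{name}", out / f"{name}.tsv")
        else:
            manifest["notes"].append("no IQM table; IQM stage skipped")

        stage = "ranking"
        rank_all = rk.ranking_consistency(study)
        write_table(rank_all.Q, out / "ranking_report.tsv")
        _record("ranking/all", out / "ranking_report.tsv")
        vendor = config.vendor or _default_vendor(study)
        if vendor is not None:
            subset = sorted(
                study.sessions.loc[
                    study.sessions["vendor"] == vendor, "scanner_id"
                ].unique()
            )
            if len(subset) >= 2:
                rank_v = rk.ranking_consistency(
                    study, scanner_subset=subset, subset_label=f"vendor:{vendor}"
                )
                write_table(rank_v.Q, out / "ranking_report_vendor.tsv")
                _record("ranking/vendor", out / "ranking_report_vendor.tsv")
        n_subjects = study.sessions["subject_id"].nunique()
        null = rk.null_baseline(
            n_subjects, n_draws=config.null_draws, seed=config.seed, mode="montecarlo"
        )
        with open(out / "null_baseline.json", "w") as fh:
            json.dump(dataclasses.asdict(null), fh, indent=2, sort_keys=True)
        _record("ranking/null", out / "null_baseline.json")

        stage = "harmonise"
        if config.method is not None:
            if config.method == "combat":
                model = fit_combat(
                    study,
                    covariates=config.covariates,
                    fit_sessions=config.fit_sessions,
                )
                harmonised = apply_combat(model, study)
            elif config.method == "covbat":
                _, harmonised = fit_apply_covbat(study, covariates=config.covariates)
            else:
                raise ContractError(f"unknown method {config.method!r}")
            hp = out / "harmonised_idps.tsv"
            h_idps = harmonised.idps.copy()
            h_idps.index.name = "session_id"
            write_table(h_idps, hp)
            _record("harmonise/idps", hp)

            stage = "evaluate"
            subset = None
            if vendor is not None:
                subset = sorted(
                    study.sessions.loc[
                        study.sessions["vendor"] == vendor, "scanner_id"
                    ].unique()
                )
                if len(subset) < 2:
                    subset = None
            ev = evaluate_harmonisation(
                study,
                harmonised,
                ddof=config.cov_ddof,
                between_policy=config.between_policy,
                vendor_subset=subset,
            )
            write_table(ev.cov_after, out / "reliability_report_harmonised.tsv")
            _record("evaluate/cov_after", out / "reliability_report_harmonised.tsv")
            write_table(
                pd.DataFrame(
                    {"ranking_before": ev.ranking_before, "ranking_after": ev.ranking_after}
                ),
                out / "ranking_pre_post.tsv",
            )
            _record("evaluate/ranking_pre_post", out / "ranking_pre_post.tsv")
            with open(out / "harmonisation_summary.json", "w") as fh:
                json.dump(ev.summary, fh, indent=2, sort_keys=True)
            _record("evaluate/summary", out / "harmonisation_summary.json")
        else:
            manifest["notes"].append("no harmonisation method; stage skipped")
    except Exception as exc:
        manifest["notes"].append(f"stage {stage!r} failed: {exc}")
        _flush()
        raise ContractError(f"stage {stage!r} failed: {exc}") from exc

    _flush()
    return manifest


# -- reporting -----------------------------------------------------------


def render_report(out_dir: str | Path) -> Path:
    """Render the figure panels of a completed run into ``report.md``.

    Missing artefacts cause their panel to be skipped with a notice rather
    than an error, so partial runs still produce a document.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .tables import read_table

    out = Path(out_dir)
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    lines = ["# Harmonisation benchmark report", ""]

    def _panel(title: str, artefact: str, plot) -> None:
        path = out / artefact
        if not path.exists():
            lines.append(f"## {title}\n\n*(panel omitted: `{artefact}` not found)*\n")
            return
        fig_path = plot(path)
        lines.append(f"## {title}\n\n![{title}]({fig_path.relative_to(out)})\n")

    def _iqm(path: Path) -> Path:
        z = read_table(path)
        fig, ax = plt.subplots(figsize=(6, 3))
        im = ax.imshow(z.to_numpy(float), cmap="RdBu_r", vmin=-2, vmax=2, aspect="auto")
        ax.set_yticks(range(len(z.index)), z.index, fontsize=6)
        ax.set_xticks(range(len(z.columns)), z.columns, rotation=90, fontsize=6)
        fig.colorbar(im, ax=ax, label="mean z-score")
        fig.tight_layout()
        p = fig_dir / "iqm_z_scanner.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        return p

    def _similarity(path: Path) -> Path:
        P = read_table(path)
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        im = axes[0].imshow(P.to_numpy(float), cmap="viridis", vmin=-1, vmax=1)
        axes[0].set_title("between-session similarity P")
        fig.colorbar(im, ax=axes[0])
        dist_path = out / "class_distributions.tsv"
        if dist_path.exists():
            dist = read_table(dist_path)
            axes[1].bar(range(len(dist)), dist["median"])
            axes[1].set_xticks(range(len(dist)), dist.index, rotation=30, fontsize=6)
            axes[1].set_ylabel("median P")
            axes[1].set_title("pair-class medians")
        fig.tight_layout()
        p = fig_dir / "similarity.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        return p

    def _bias(path: Path) -> Path:
        bias = read_table(path)
        fig, ax = plt.subplots(figsize=(7, 3))
        for sub, row in bias.iterrows():
            ax.plot(row.to_numpy(float), lw=0.5, label=str(sub))
        ax.axhline(0, color="k", lw=0.5)
        ax.set_ylabel("bias [%]")
        ax.set_xlabel("IDP")
        ax.legend(fontsize=6)
        fig.tight_layout()
        p = fig_dir / "bias.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        return p

    def _cov(path: Path) -> Path:
        rep = read_table(path)
        fig, axes = plt.subplots(2, 1, figsize=(7, 5), sharex=False)
        for col, colour in (
            ("cov_within_scanner", "tab:blue"),
            ("cov_between_scanner", "tab:green"),
            ("cov_biological", "tab:orange"),
        ):
            axes[0].plot(rep[col].to_numpy(float), ".", ms=2, color=colour, label=col)
        axes[0].set_yscale("log")
        axes[0].set_ylabel("CoV")
        axes[0].legend(fontsize=6)
        axes[1].plot(rep["relative_difference_pct"].to_numpy(float), ".", ms=2, color="tab:red")
        axes[1].axhline(100, ls="--", color="k", lw=0.5)
        axes[1].set_ylabel("relative difference [%]")
        axes[1].set_xlabel("IDP")
        fig.tight_layout()
        p = fig_dir / "cov_profile.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        return p

    def _ranking(path: Path) -> Path:
        Q = read_table(path)
        per_idp = Q.apply(pd.to_numeric, errors="coerce").median(axis=0)
        fig, ax = plt.subplots(figsize=(7, 3))
        null_path = out / "null_baseline.json"
        if null_path.exists():
            null = json.loads(null_path.read_text())
            ax.axhspan(null["q25"], null["q75"], color="red", alpha=0.2, label="null IQR")
        ax.plot(per_idp.to_numpy(float), ".", ms=2)
        ax.set_ylabel("median Q across scanner pairs")
        ax.set_xlabel("IDP")
        ax.legend(fontsize=6)
        fig.tight_layout()
        p = fig_dir / "ranking.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        return p

    def _prepost(path: Path) -> Path:
        before = read_table(out / "reliability_report.tsv")
        after = read_table(path)
        fig, axes = plt.subplots(1, 2, figsize=(8, 4))
        axes[0].scatter(
            before["cov_between_scanner"], after["cov_between_scanner"], s=4
        )
        lim = np.nanmax(before["cov_between_scanner"].to_numpy(float))
        axes[0].plot([0, lim], [0, lim], "k--", lw=0.5)
        axes[0].set_xlabel("between-scanner CoV before")
        axes[0].set_ylabel("after")
        rp = out / "ranking_pre_post.tsv"
        if rp.exists():
            pp = read_table(rp)
            axes[1].scatter(pp["ranking_before"], pp["ranking_after"], s=4)
            axes[1].plot([-1, 1], [-1, 1], "k--", lw=0.5)
            axes[1].set_xlabel("median Q before")
            axes[1].set_ylabel("after")
        fig.tight_layout()
        p = fig_dir / "harmonisation.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        return p

    _panel("IQM variability across scanners", "iqm_z_scanner.tsv", _iqm)
    _panel("Between-session similarity", "P.tsv", _similarity)
    _panel("Scanner bias", "bias_report.tsv", _bias)
    _panel("Coefficient-of-variation profile", "reliability_report.tsv", _cov)
    _panel("Subject-ranking consistency", "ranking_report.tsv", _ranking)
    _panel(
        "Harmonisation: before vs after",
        "reliability_report_harmonised.tsv",
        _prepost,
    )

    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report
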