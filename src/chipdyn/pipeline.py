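"""End-to-end pipeline driver: simulate → call → filter → annotate CHIP →
fit trajectories → validate → associate.

Each stage reads only :class:`~chipdyn.config.PipelineConfig` for thresholds,
writes plain-text outputs (TSV/VCF/JSON) into the run directory, and records
per-stage record counts in ``run_manifest.json``.  Reruns with the same config
and seed are output-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chip import (VariantAnnotation, annotate_driver, chip_status_table,
                   default_whitelist, prevalence_by_age)
from .config import PipelineConfig
from .simulate import simulate_cohort
from .trajectories import (assemble_trajectories, classify_trajectory,
                           compare_gene_groups, competition_report,
                           exclude_high_start, fit_trajectory, select_dominant,
                           trajectory_table, MAJOR_CHIP_GENES)
from .validation import estimate_error_rate
from .variants import (SiteObservation, apply_call_filters, call_variants,
                       filter_recurrent_artifacts)
from .vcfio import write_observation_tsv, write_vcf
from .association import (ModelError, cross_sectional_model,
                          longitudinal_growth_model)

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages on a simulated cohort; returns the run manifest dict."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"chipdyn_version": __version__, "seed": config.seed,
                      "config": config.to_dict(), "stages": {}}

    # ---- simulate -------------------------------------------------------
    stage = "simulate"
    try:
        sim = simulate_cohort(config.sim)
        obs_dir = out / "observations"
        obs_dir.mkdir(exist_ok=True)
        truth = pd.DataFrame(
            [
                {
                    "subject_id": c.subject_id, "gene": c.gene,
                    "variant_id": c.variant_id, "beta_true": c.beta_true,
                    "vaf_baseline": c.vaf_baseline, "age_baseline": c.age_baseline,
                }
                for c in sim.truth
            ]
        )
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        sim.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        sim.annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
        for (sid, tp), obs in sorted(sim.observations.items()):
            stem = obs_dir / f"{sid}_{tp}"
            write_observation_tsv(f"{stem}.tsv", obs)
            site_obs = [
                SiteObservation(chrom=str(r.chrom), pos=int(r.pos), ref=r.ref,
                                alt=r.alt, depth=int(r.depth),
                                alt_count=int(r.alt_count))
                for r in obs.itertuples()
            ]
            write_vcf(f"{stem}.vcf", site_obs)
        manifest["stages"][stage] = {
            "n_subjects": int(sim.manifest["subject_id"].nunique()),
            "n_samples": int(len(sim.manifest)),
            "n_true_clones": int(len(sim.truth)),
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # ---- process: call + filter ----------------------------------------
    stage = "process"
    try:
        rows = []
        for (sid, tp), obs in sorted(sim.observations.items()):
            for r in obs.itertuples():
                so = SiteObservation(chrom=str(r.chrom), pos=int(r.pos), ref=r.ref,
                                     alt=r.alt, depth=int(r.depth),
                                     alt_count=int(r.alt_count))
                call = call_variants(so, config.error_rate, config.caller_alpha)
                call = apply_call_filters(call, config.min_depth, config.min_alt,
                                          config.min_vaf)
                rows.append(
                    {
                        "sample_id": f"{sid}:{tp}", "subject_id": sid,
                        "timepoint": tp, "variant_id": so.variant_id,
                        "gene": r.gene, "chrom": so.chrom, "pos": so.pos,
                        "ref": so.ref, "alt": so.alt, "depth": so.depth,
                        "alt_count": so.alt_count, "vaf": so.vaf,
                        "p_value": call.p_value, "is_candidate": call.is_candidate,
                        "low_coverage": call.low_coverage,
                        "low_alt_support": call.low_alt_support,
                        "low_vaf": call.low_vaf,
                    }
                )
        calls = pd.DataFrame(rows)
        if calls.empty:
            calls = pd.DataFrame(columns=[
                "sample_id", "subject_id", "timepoint", "variant_id", "gene",
                "chrom", "pos", "ref", "alt", "depth", "alt_count", "vaf",
                "p_value", "is_candidate", "low_coverage", "low_alt_support",
                "low_vaf"])
        calls = filter_recurrent_artifacts(
            calls,
            sample_fraction=config.artifact_sample_fraction,
            vaf_window=config.artifact_vaf_window,
            group_col="subject_id" if config.artifact_by_subject else "sample_id",
        )
        calls["is_pass"] = (
            calls["is_candidate"]
            & ~calls["low_coverage"] & ~calls["low_alt_support"]
            & ~calls["low_vaf"] & ~calls["recurrent_artifact"]
        )
        calls.to_csv(out / "calls.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_site_observations": int(len(calls)),
            "n_candidates": int(calls["is_candidate"].sum()),
            "removed_low_coverage": int((calls["is_candidate"] & calls["low_coverage"]).sum()),
            "removed_low_alt_support": int((calls["is_candidate"] & calls["low_alt_support"]).sum()),
            "removed_low_vaf": int((calls["is_candidate"] & calls["low_vaf"]).sum()),
            "removed_recurrent_artifact": int((calls["is_candidate"] & calls["recurrent_artifact"]).sum()),
            "n_pass": int(calls["is_pass"].sum()),
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # ---- chip-call ------------------------------------------------------
    stage = "chip-call"
    try:
        whitelist = default_whitelist()
        whitelist.to_yaml(out / "whitelist.yaml")
        ann_by_vid = {
            r.variant_id: VariantAnnotation(
                variant_id=r.variant_id, gene=r.gene,
                functional_class=r.functional_class,
                protein_change=r.protein_change, pop_af=float(r.pop_af),
            )
            for r in sim.annotations.itertuples()
        }
        passing = calls[calls["is_pass"]]
        driver_mask = [
            annotate_driver(None, ann_by_vid.get(vid), whitelist)
            for vid in passing["variant_id"]
        ]
        drivers = passing[np.array(driver_mask, dtype=bool)].copy() if len(passing) else passing.copy()
        driver_variants = set(drivers["variant_id"]) if len(drivers) else set()
        drivers["protein_change"] = [
            ann_by_vid[v].protein_change for v in drivers["variant_id"]
        ]
        drivers.to_csv(out / "drivers.tsv", sep="\t", index=False)

        statuses = chip_status_table(
            drivers, sim.manifest, config.chip_vaf, config.large_clone_vaf
        )
        statuses.to_csv(out / "chip_status.tsv", sep="\t", index=False)
        first = (
            sim.manifest.sort_values("age").groupby("subject_id").head(1)
            [["subject_id", "timepoint"]]
        )
        baseline = statuses.merge(first, on=["subject_id", "timepoint"])
        prevalence = prevalence_by_age(baseline, config.age_bins)
        prevalence.to_csv(out / "prevalence.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_driver_calls": int(len(drivers)),
            "n_driver_variants": len(driver_variants),
            "n_chip_positive_baseline": int(baseline["chip_positive"].sum()),
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # ---- trajectories ---------------------------------------------------
    stage = "trajectories"
    try:
        # full longitudinal series for every driver site (all assayed visits)
        driver_long = calls[calls["variant_id"].isin(driver_variants)].copy()
        driver_long["protein_change"] = [
            ann_by_vid[v].protein_change for v in driver_long["variant_id"]
        ]
        trajs = assemble_trajectories(
            driver_long, sim.manifest,
            min_timepoints=config.traj_min_timepoints,
            min_tracking_vaf=config.traj_min_tracking_vaf,
            min_depth=config.traj_min_depth,
            min_alt=config.traj_min_alt,
        )
        trajs = exclude_high_start(trajs, config.max_start_vaf)
        trajs = [t for t in trajs if len({o.age for o in t.observations}) >= 2]
        fits = []
        for t in trajs:
            f = fit_trajectory(t, config.vaf_floor)
            f.label = classify_trajectory(f, config.p_threshold)
            fits.append(f)

        dominant: dict[str, str] = {}
        dominant_rows = []
        by_subject: dict[str, list[int]] = {}
        for i, t in enumerate(trajs):
            by_subject.setdefault(t.subject_id, []).append(i)
        for sid, idx in sorted(by_subject.items()):
            dom = select_dominant([trajs[i] for i in idx], [fits[i] for i in idx])
            if dom is None:
                continue
            dominant[sid] = dom.trajectory.variant_id
            dominant_rows.append(
                {
                    "subject_id": sid, "variant_id": dom.trajectory.variant_id,
                    "gene": dom.trajectory.gene,
                    "delta_log10_vaf": dom.delta_log10_vaf,
                    "label": dom.fit.label if dom.fit else None,
                    "beta": dom.fit.beta if dom.fit else np.nan,
                }
            )
        traj_df = trajectory_table(trajs, fits, dominant)
        traj_df.to_csv(out / "trajectories.tsv", sep="\t", index=False)
        dominants = pd.DataFrame(
            dominant_rows,
            columns=["subject_id", "variant_id", "gene", "delta_log10_vaf",
                     "label", "beta"],
        )
        dominants.to_csv(out / "dominant_clones.tsv", sep="\t", index=False)
        comp = competition_report(trajs, fits, config.chip_vaf)
        comp.to_csv(out / "competition.tsv", sep="\t", index=False)

        group_stats: dict = {}
        dom_growing = dominants[dominants["label"] == "growing"]
        has_both = (
            len(dom_growing) > 1
            and dom_growing["gene"].isin(MAJOR_CHIP_GENES).any()
            and (~dom_growing["gene"].isin(MAJOR_CHIP_GENES)).any()
        )
        if has_both:
            u, p = compare_gene_groups(dom_growing)
            group_stats["mannwhitney_major_vs_other"] = {"U": u, "p": p}
        with open(out / "gene_group_stats.json", "w") as fh:
            json.dump(group_stats, fh, indent=2)

        label_counts = traj_df["label"].value_counts(dropna=True).to_dict()
        manifest["stages"][stage] = {
            "n_trajectories": int(len(trajs)),
            "labels": {str(k): int(v) for k, v in label_counts.items()},
            "n_dominant": int(len(dominants)),
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # ---- validate: pooled error rate from invariant background sites ----
    stage = "validate"
    try:
        inv_frames = [
            obs.attrs.get("invariant_sites")
            for (_, _), obs in sorted(sim.observations.items())
            if obs.attrs.get("invariant_sites") is not None
        ]
        validation: dict = {}
        if inv_frames:
            pooled = pd.concat(inv_frames, ignore_index=True)
            est = estimate_error_rate(pooled)
            validation["error_rate"] = est.rate
            validation["error_rate_one_in_n_bp"] = est.one_in_n_bp
            validation["n_invariant_sites"] = est.n_sites
        with open(out / "validation.json", "w") as fh:
            json.dump(validation, fh, indent=2)
        manifest["stages"][stage] = {"n_invariant_sites": validation.get("n_invariant_sites", 0)}
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # ---- associate ------------------------------------------------------
    stage = "associate"
    try:
        subj = (
            sim.manifest.sort_values("age")
            .groupby("subject_id")
            .first()
            .reset_index()
            .rename(columns={"draw_year": "first_visit_year"})
        )
        base = baseline.merge(
            subj[["subject_id", "bmi", "smoking", "race_ethnicity", "first_visit_year"]],
            on="subject_id",
        )
        base["chip_positive"] = base["n_clones_2pct"] >= 1
        base["large_clone"] = base["n_clones_10pct"] >= 1
        max_vaf = (
            drivers.merge(first, on=["subject_id", "timepoint"])
            .groupby("subject_id")["vaf"].max()
        ) if len(drivers) else pd.Series(dtype=float)
        base["log10_vaf"] = np.log10(base["subject_id"].map(max_vaf))

        assoc_frames = []
        for outcome in ("chip_prevalence", "large_clone_prevalence", "log10_vaf"):
            try:
                res = cross_sectional_model(base, outcome)
                tab = res.coefficients.assign(outcome=outcome, model=res.model,
                                              n_used=res.n_used)
                assoc_frames.append(tab)
            except ModelError as e:
                logger.warning("cross-sectional %s skipped: %s", outcome, e)
        try:
            deltas = dominants.merge(
                subj[["subject_id", "age", "bmi", "smoking", "race_ethnicity",
                      "first_visit_year"]],
                on="subject_id",
            )
            res = longitudinal_growth_model(deltas)
            assoc_frames.append(
                res.coefficients.assign(outcome="delta_log10_vaf",
                                        model=res.model, n_used=res.n_used)
            )
        except ModelError as e:
            logger.warning("growth model skipped: %s", e)
        assoc = (
            pd.concat(assoc_frames, ignore_index=True)
            if assoc_frames
            else pd.DataFrame(columns=["term", "estimate", "se", "p",
                                       "outcome", "model", "n_used"])
        )
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"n_models": int(assoc["outcome"].nunique())
                                     if len(assoc) else 0}
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
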