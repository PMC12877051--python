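"""End-to-end orchestration: synthetic or file-based cohorts through
preprocessing, ignition metrics, tumor mapping, group inference, RSN
analysis and cognition coupling, with a checksummed output manifest.

Stage order mirrors the analysis structure: subject level, region level,
then resting-state networks. The window length is resolved per subject
from its TR (7 TRs at 2400 ms, 8 at 2100 ms), and every design default in
effect (filter order, winsorizing, delta sign, BH family) is echoed into
the manifest so a run is self-describing. Inputs are never mutated; all
artifacts land under the configured output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cognition as cog
from . import inference, io, rsn, tumor
from .containers import ParcellatedBold
from .ignition import IgnitionParams, compute_profile, window_length
from .lmm import LmmError, fit_lmm
from .preprocess import PreprocessParams, run_preprocess
from .synthetic import CohortSpec, generate_bold, generate_cognition, generate_tumor_masks

logger = logging.getLogger(__name__)

KNOWN_TRS = (2100, 2400)


@dataclass
class RunConfig:
    """Fully serializable run description; same config + seed => same run."""

    mode: str = "synthetic"  # synthetic | parcellated-tsv | nifti
    output_dir: str = "ignite-output"
    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    preprocess: dict = field(default_factory=dict)  # PreprocessParams overrides
    ignition_normalized: bool = False
    prob_thresh: float = tumor.PROB_THRESHOLD
    r_min: float = rsn.R_THRESHOLD
    sensitivity_parent: str = "laplace"
    signals: dict = field(default_factory=dict)  # subject -> TSV path (tsv mode)
    images: dict = field(default_factory=dict)  # subject -> 4D NIfTI (nifti mode)
    atlas: str = ""  # atlas NIfTI (nifti mode)
    masks: dict = field(default_factory=dict)  # subject -> tumor-mask NIfTI
    phenotype: str = ""  # phenotype TSV (non-synthetic modes)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def validate_inputs(config: RunConfig) -> dict:
    """Pre-flight checks; returns {'errors': [...], 'warnings': [...]}."""
    errors, warnings = [], []
    if config.mode not in ("synthetic", "parcellated-tsv", "nifti"):
        errors.append(f"unknown mode {config.mode!r}")
    if config.mode == "synthetic":
        try:
            spec = CohortSpec(seed=config.seed, **config.cohort)
        except Exception as exc:  # validation error names the field
            errors.append(str(exc))
            return {"errors": errors, "warnings": warnings}
        for sub in spec.subjects:
            tr = spec.subject_tr(sub)
            if tr not in KNOWN_TRS:
                warnings.append(
                    f"{sub}: TR {tr} ms not in {KNOWN_TRS}; window length "
                    f"generalized to round(16800/TR) = {window_length(tr)} TRs"
                )
        return {"errors": errors, "warnings": warnings}
    pheno_path = Path(config.phenotype) if config.phenotype else None
    if pheno_path is None or not pheno_path.exists():
        errors.append("phenotype table missing")
        return {"errors": errors, "warnings": warnings}
    pheno = io.read_phenotype_tsv(pheno_path)
    for col in ("subject_id", "group", "tr_ms"):
        if col not in pheno.columns:
            errors.append(f"phenotype missing column {col!r}")
    if "group" in pheno.columns and pheno["group"].isna().any():
        bad = pheno.loc[pheno["group"].isna(), "subject_id"].tolist()
        errors.append(f"missing group label for subjects: {bad}")
    if "tr_ms" in pheno.columns:
        for _, row in pheno.iterrows():
            tr = row["tr_ms"]
            if tr not in KNOWN_TRS:
                warnings.append(
                    f"{row.get('subject_id', '?')}: TR {tr} ms not in "
                    f"{KNOWN_TRS}; window length generalized to "
                    f"round(16800/TR) = {window_length(tr)} TRs"
                )
    sources = config.signals if config.mode == "parcellated-tsv" else config.images
    for sub, path in sources.items():
        if not Path(path).exists():
            errors.append(f"{sub}: input file {path} not found")
    return {"errors": errors, "warnings": warnings}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _load_cohort(config: RunConfig):
    """Returns (cohort, groups, overlaps, latency, truth-or-None)."""
    if config.mode == "synthetic":
        spec = CohortSpec(seed=config.seed, **config.cohort)
        cohort, truth = generate_bold(spec)
        overlaps = generate_tumor_masks(spec)
        return cohort, dict(spec.groups), overlaps, None, (spec, truth)
    pheno = io.read_phenotype_tsv(config.phenotype)
    groups, latency, cohort, overlaps = {}, {}, {}, {}
    tr_of = dict(zip(pheno["subject_id"], pheno["tr_ms"]))
    for _, row in pheno.iterrows():
        groups[row["subject_id"]] = row["group"]
        if "rvp_mean_latency" in pheno.columns and pd.notna(row.get("rvp_mean_latency")):
            latency[row["subject_id"]] = float(row["rvp_mean_latency"])
    if config.mode == "parcellated-tsv":
        for sub, path in config.signals.items():
            cohort[sub] = io.read_signals_tsv(path, tr_ms=float(tr_of[sub]), subject_id=sub)
    else:
        for sub, path in config.images.items():
            cohort[sub] = io.extract_parcel_signals(
                path, config.atlas, tr_ms=float(tr_of[sub]), subject_id=sub
            )
        if config.masks:
            atlas = np.asarray(io.load_nifti(config.atlas)).round().astype(int)
            for sub, mpath in config.masks.items():
                overlaps[sub] = tumor.mask_to_region_fraction(
                    io.load_nifti(mpath), atlas, config.prob_thresh, subject_id=sub
                )
    return cohort, groups, overlaps, latency or None, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    A stage failure marks the stage failed in the manifest, skips dependent
    stages, and raises :class:`PipelineError` at the end.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    pp = PreprocessParams(**config.preprocess)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "design_defaults": {
            "filter": f"butterworth order {pp.filter_order}, zero-phase",
            "outliers": pp.outlier_mode,
            "delta_sign": "subject - control mean (negative = reduction)",
            "bh_family": "three pairwise comparisons within each metric",
            "window": "7 TRs @ 2400 ms / 8 TRs @ 2100 ms (16.8 s)",
        },
        "stages": {},
        "artifacts": {},
    }
    state: dict = {}

    def stage(name: str, func, depends: tuple = ()):
        for dep in depends:
            if manifest["stages"].get(dep) != "ok":
                manifest["stages"][name] = f"skipped (needs {dep})"
                return
        try:
            func()
            manifest["stages"][name] = "ok"
        except Exception as exc:
            logger.exception("stage %s failed", name)
            manifest["stages"][name] = f"failed: {exc}"

    # ---- load / synthesize -------------------------------------------
    def s_load():
        cohort, groups, overlaps, latency, synth = _load_cohort(config)
        state.update(cohort=cohort, groups=groups, overlaps=overlaps,
                     latency=latency, synth=synth)

    stage("load", s_load)

    # ---- preprocess + region-level ignition --------------------------
    def s_ignition():
        profiles = {}
        prof_rows = []
        for sub, bold in state["cohort"].items():
            _, raster = run_preprocess(bold, pp)
            params = IgnitionParams.for_tr(
                bold.tr_ms, integration_normalized=config.ignition_normalized
            )
            prof = compute_profile(raster, params)
            profiles[sub] = prof
            for i, rid in enumerate(prof.region_ids):
                prof_rows.append(
                    {"subject": sub, "region_id": rid,
                     "ignition": prof.ignition[i],
                     "metastability": prof.metastability[i],
                     "n_events": prof.n_events[i]}
                )
        state["profiles"] = profiles
        _write_tsv(pd.DataFrame(prof_rows), outdir / "region_profiles.tsv")
        summary = pd.DataFrame(
            [
                {"subject": sub, "group": state["groups"][sub],
                 "tr_ms": state["cohort"][sub].tr_ms,
                 "window_tr": window_length(state["cohort"][sub].tr_ms),
                 "mean_ignition": prof.mean_ignition,
                 "mean_metastability": prof.mean_metastability}
                for sub, prof in profiles.items()
            ]
        )
        state["summary"] = summary
        _write_tsv(summary, outdir / "subject_summary.tsv")

    stage("ignition", s_ignition, depends=("load",))

    # ---- subject-level inference -------------------------------------
    def s_subject_stats():
        summary = state["summary"]
        frames = []
        for metric in ("mean_ignition", "mean_metastability"):
            res = inference.mannwhitney_bh(
                dict(zip(summary["subject"], summary[metric])), state["groups"]
            )
            res.insert(0, "metric", metric)
            frames.append(res)
        _write_tsv(pd.concat(frames), outdir / "subject_level_stats.tsv")
        sizes = summary.groupby("group").size()
        sens = {}
        for grp in ("meningioma", "glioma"):
            if grp in sizes and "control" in sizes:
                spec = inference.SensitivitySpec(
                    n1=int(sizes[grp]), n2=int(sizes["control"]),
                    parent_distribution=config.sensitivity_parent,
                )
                d = inference.sensitivity_effect_size(spec)
                sens[grp] = {"n1": spec.n1, "n2": spec.n2, "min_effect_d": round(d, 2)}
        (outdir / "sensitivity.json").write_text(json.dumps(sens, indent=2))

    stage("subject_stats", s_subject_stats, depends=("ignition",))

    # ---- region level: deltas, bins, LMM -----------------------------
    def s_region_level():
        delta = tumor.build_delta_table(
            state["profiles"], state["groups"], state["overlaps"] or {}
        )
        state["delta"] = delta
        _write_tsv(delta, outdir / "delta_table.tsv")
        bins = []
        for grp in ("meningioma", "glioma"):
            if (delta["group"] == grp).any():
                b = tumor.bin_summary(delta, grp)
                b.insert(0, "group", grp)
                bins.append(b)
        if bins:
            _write_tsv(pd.concat(bins), outdir / "bin_summary.tsv")
        for grp in ("meningioma", "glioma"):
            part = delta[delta["group"] == grp]
            if part.empty:
                continue
            for response in ("delta_ignition", "delta_metastability"):
                try:
                    fit = fit_lmm(part, response=response)
                except (ValueError, LmmError) as exc:
                    logger.warning("LMM %s/%s skipped: %s", grp, response, exc)
                    continue
                report = {
                    "formula": fit.formula, "structure": fit.structure,
                    "converged": fit.converged, "params": fit.params,
                    "se": fit.se, "t": fit.tvalues, "df": fit.df,
                    "p": fit.pvalues, "random_sd": fit.re_sd,
                    "corr_subject": None if np.isnan(fit.corr_subject) else fit.corr_subject,
                    "sigma": fit.sigma, "n_obs": fit.n_obs,
                    "messages": fit.messages,
                }
                (outdir / f"lmm_{grp}_{response}.json").write_text(
                    json.dumps(report, indent=2)
                )

    stage("region_level", s_region_level, depends=("ignition",))

    # ---- RSN level ---------------------------------------------------
    def s_rsn():
        if state["synth"] is not None:
            assignment = state["synth"][0].network_assignment
        else:
            n_regions = next(iter(state["cohort"].values())).n_regions
            assignment = np.repeat(np.arange(7), -(-n_regions // 7))[:n_regions]
        metrics = rsn.network_metrics(state["cohort"], assignment, pp)
        state["net_metrics"] = metrics
        _write_tsv(metrics, outdir / "network_metrics.tsv")
        groups = state["groups"]
        members: dict = {}
        for sub, grp in groups.items():
            members.setdefault(grp, []).append(sub)
        edge_frames = []
        for grp, subs in members.items():
            for mode in ("ign-ign", "meta-meta", "ign-meta"):
                edges, graph = rsn.metric_correlation_graph(
                    metrics, mode, subs, r_min=config.r_min
                )
                edges.insert(0, "mode", mode)
                edges.insert(0, "group", grp)
                edge_frames.append(edges)
                import networkx as nx

                nx.write_graphml(
                    graph, outdir / f"rsn_graph_{grp}_{mode}.graphml"
                )
        _write_tsv(pd.concat(edge_frames), outdir / "rsn_edges.tsv")
        corr_rows = []
        for grp, subs in members.items():
            for level in ("subject", "network-region"):
                try:
                    r, p = rsn.subject_vs_region_correlation(metrics, level, subs)
                except ValueError as exc:
                    logger.warning("%s/%s correlation skipped: %s", grp, level, exc)
                    continue
                corr_rows.append({"group": grp, "level": level, "r": r, "p": p})
        _write_tsv(pd.DataFrame(corr_rows), outdir / "rsn_correlations.tsv")
        if state["overlaps"]:
            _write_tsv(
                rsn.affected_network_counts(state["overlaps"], assignment),
                outdir / "affected_networks.tsv",
            )

    stage("rsn", s_rsn, depends=("ignition",))

    # ---- cognition ---------------------------------------------------
    def s_cognition():
        latency = state["latency"]
        if latency is None and state["synth"] is not None:
            _, truth = state["synth"]
            latency = generate_cognition(
                truth, dict(zip(state["summary"]["subject"], state["summary"]["mean_ignition"]))
            )
        if latency is None:
            manifest["stages"]["cognition"] = "skipped (no latency scores)"
            return
        table = cog.build_cognition_table(latency, state["groups"], state["net_metrics"])
        _write_tsv(table, outdir / "cognition_table.tsv")
        report = {"kruskal_wallis": cog.kruskal_wallis(table), "networks": {}}
        for net in cog.COGNITION_NETWORKS:
            entry: dict = {"correlations": {}}
            for grp in set(state["groups"].values()):
                try:
                    r, p = cog.ignition_latency_correlation(table, net, grp)
                    entry["correlations"][grp] = {"r": r, "p": p}
                except ValueError as exc:
                    entry["correlations"][grp] = {"error": str(exc)}
            try:
                res = cog.interaction_model(table, net)
                entry["interaction"] = {
                    "coefficients": res["coefficients"].to_dict(orient="index"),
                    "anova_typ3": res["anova_typ3"].to_dict(orient="index"),
                }
            except ValueError as exc:
                entry["interaction"] = {"error": str(exc)}
            report["networks"][net] = entry
        (outdir / "cognition_stats.json").write_text(json.dumps(report, indent=2, default=float))

    stage("cognition", s_cognition, depends=("rsn",))

    # ---- manifest ----------------------------------------------------
    for path in sorted(outdir.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest["artifacts"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    failed = [s for s, st in manifest["stages"].items() if st.startswith("failed")]
    if failed:
        raise PipelineError(f"stage(s) failed: {failed}", manifest)
    return manifest


class PipelineError(RuntimeError):
    def __init__(self, message: str, manifest: dict):
        super().__init__(message)
        self.manifest = manifest
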