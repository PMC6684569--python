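"""End-to-end orchestration: simulate -> screen -> dual-regress ->
similarity -> graph -> network-FC -> inference -> mediation.

A single :class:`RunConfig` (loadable from YAML) drives every stage; the
master seed is the only source of randomness, with per-stage and
per-subject child streams derived from it, so identical config + seed
gives byte-identical output tables.  Every table is written as TSV with a
YAML provenance sidecar carrying the config, stage checksums, and the
conventions that affect values (masking rule for eta-squared, disconnected
-graph conventions, FDR families).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import confounds, dualreg, graphnet, inference, io, netfc, similarity, synthcohort
from .exceptions import ConfigurationError
from .parcellation import (
    Parcellation,
    default_parcellation,
    make_parcellation,
    validate_parcellation,
)

ALL_STAGES = (
    "simulate",
    "screen",
    "dualreg",
    "similarity",
    "graph",
    "netfc",
    "infer",
    "mediate",
)


@dataclass
class RunConfig:
    out_dir: str = "connlife_run"
    seed: int = 0
    simulate: synthcohort.CohortConfig = field(
        default_factory=synthcohort.CohortConfig
    )
    mean_fd_mm: float = 0.2
    spike_fraction: float = 0.20
    reference_cutoff_age: float = 30.0
    graph_thresholds: tuple[float, ...] = graphnet.DEFAULT_THRESHOLDS
    fdr_q: float = 0.05
    n_boot: int = 10000
    stages: tuple[str, ...] = ALL_STAGES
    use_dual_regression: bool = True
    preprocess_timeseries: bool = True
    compute_graph_metrics: bool = True
    write_timeseries: bool = False
    write_maps: bool = False
    reduced_parcellation: dict | None = None  # {"counts": {...}, "n_other": int}

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
        if not (0 < self.fdr_q < 1):
            raise ConfigurationError("fdr_q must be in (0, 1)")

    def parcellation(self) -> Parcellation:
        if self.reduced_parcellation:
            return make_parcellation(
                self.reduced_parcellation["counts"],
                self.reduced_parcellation.get("n_other", 0),
            )
        return default_parcellation()


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulate", {})
    if "age_range" in sim:
        sim["age_range"] = tuple(sim["age_range"])
    if "grid_shape" in sim:
        sim["grid_shape"] = tuple(sim["grid_shape"])
    cfg = RunConfig(**{k: v for k, v in raw.items() if k != "simulate"})
    if "seed" in raw and "seed" not in sim:
        sim["seed"] = raw["seed"]
    cfg.simulate = synthcohort.CohortConfig(**sim)
    if "stages" in raw:
        cfg.stages = tuple(raw["stages"])
    if "graph_thresholds" in raw:
        cfg.graph_thresholds = tuple(raw["graph_thresholds"])
    return cfg


@dataclass
class RunReport:
    out_dir: Path
    tables: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def _seeded_simulate(cfg: RunConfig):
    sim = cfg.simulate
    if sim.seed != cfg.seed:
        sim = synthcohort.CohortConfig(**{**asdict(sim), "seed": cfg.seed})
        if isinstance(sim.age_range, list):  # asdict round-trip
            sim = synthcohort.CohortConfig(
                **{**asdict(sim), "age_range": tuple(sim.age_range)}
            )
    return synthcohort.generate_cohort(sim)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Run the configured stages; returns the report with all tables."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(out_dir=out)
    stages = set(cfg.stages)
    parc = cfg.parcellation()

    subjects, truth = _seeded_simulate(cfg)
    templates = synthcohort.make_templates(
        parc.rsn_networks, cfg.simulate.grid_shape, seed=cfg.seed
    )
    demo = synthcohort.demographics_frame(subjects)

    if "simulate" in stages:
        report.checksums["demographics"] = io.save_table(demo, out / "demographics.tsv")
        report.tables["demographics"] = demo
        io.save_provenance(synthcohort.truth_to_dict(truth), out / "ground_truth.yaml")
        motion_dir = out / "motion"
        motion_dir.mkdir(exist_ok=True)
        for s in subjects:
            io.save_motion(
                synthcohort.generate_motion_trace(s, truth),
                motion_dir / f"{s.subject_id}_motion.tsv",
            )
        if cfg.write_maps:
            for s in subjects:
                mdir = out / "maps" / s.subject_id
                mdir.mkdir(parents=True, exist_ok=True)
                for lab, m in synthcohort.generate_spatial_maps(
                    s, truth, templates
                ).items():
                    io.save_map(m, mdir / f"{lab}.nii.gz")
        if cfg.write_timeseries:
            tdir = out / "timeseries"
            tdir.mkdir(exist_ok=True)
            for s in subjects:
                ts = synthcohort.generate_node_timeseries(s, parc, truth)
                np.savetxt(
                    tdir / f"{s.subject_id}_ts.tsv", ts.values,
                    fmt="%.6f", delimiter="\t",
                )

    # --- motion screening ----------------------------------------------
    if "screen" in stages:
        rows = []
        included = []
        for s in subjects:
            trace = synthcohort.generate_motion_trace(s, truth)
            fd = confounds.framewise_displacement(
                trace, cfg.simulate.head_radius_mm
            )
            dec = confounds.screen_subject(
                fd, cfg.mean_fd_mm, cfg.spike_fraction
            )
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "mean_fd": dec.mean_fd,
                    "spike_fraction": dec.spike_fraction,
                    "included": dec.include,
                    "reasons": "; ".join(dec.reasons),
                }
            )
            if dec.include:
                included.append(s)
        screen_df = pd.DataFrame(rows)
        report.tables["screening"] = screen_df
        report.checksums["screening"] = io.save_table(screen_df, out / "screening.tsv")
        subjects_in = included
    else:
        subjects_in = list(subjects)

    if not subjects_in:
        raise ConfigurationError("no subject survived motion screening")
    demo_in = synthcohort.demographics_frame(subjects_in)
    age = demo_in["age"].to_numpy()
    sex = demo_in["sex"].to_numpy(dtype=float)
    ace = demo_in["ace_r_total"].to_numpy()

    downstream = stages & {"dualreg", "similarity", "graph", "netfc", "infer", "mediate"}
    if not downstream:
        _finish(report, cfg)
        return report

    # --- subject maps (direct or via dual regression) ------------------
    need_maps = stages & {"dualreg", "similarity", "infer", "mediate"}
    subj_maps: dict[str, dict[str, dualreg.SpatialMap]] = {}
    if need_maps:
        dr = dualreg.DualRegression().fit(templates)
        for s in subjects_in:
            maps = synthcohort.generate_spatial_maps(s, truth, templates)
            if cfg.use_dual_regression and "dualreg" in stages:
                data = synthcohort.generate_voxel_data(s, truth, maps)
                maps = dr.subject_maps(data)
            subj_maps[s.subject_id] = maps

    # --- similarity -----------------------------------------------------
    eta_wide = None
    if stages & {"similarity", "infer", "mediate"}:
        ages_by_id = dict(zip(demo_in["subject_id"], demo_in["age"]))
        ref = similarity.build_reference(
            subj_maps, ages_by_id, cfg.reference_cutoff_age
        )
        eta_df = similarity.similarity_table(subj_maps, ref)
        report.tables["similarity"] = eta_df
        report.checksums["similarity"] = io.save_table(eta_df, out / "similarity.tsv")
        eta_wide = eta_df.pivot(
            index="subject_id", columns="rsn_label", values="eta_sq"
        ).loc[demo_in["subject_id"]]
        report.meta["reference"] = {
            "cutoff_age": ref.cutoff_age,
            "n_reference_subjects": ref.n_reference_subjects,
            "mask": "whole grid (all voxels)",
        }

    # --- connectivity, graph metrics, network FC ------------------------
    conns: dict[str, graphnet.ConnectivityMatrix] = {}
    if stages & {"graph", "netfc", "infer", "mediate"}:
        node_order = tuple(r[0] for r in parc.rois)
        for s in subjects_in:
            ts = synthcohort.generate_node_timeseries(s, parc, truth)
            if cfg.preprocess_timeseries:
                trace = synthcohort.generate_motion_trace(s, truth)
                design = confounds.build_confound_design(trace)
                ts = confounds.bandpass(confounds.regress_confounds(ts, design))
            conns[s.subject_id] = graphnet.build_connectivity(ts, node_order)

    metrics_wide = None
    if "graph" in stages and cfg.compute_graph_metrics:
        frames = [
            graphnet.metric_sweep(conns[s.subject_id], cfg.graph_thresholds,
                                  seed=cfg.seed, subject_id=s.subject_id)
            for s in subjects_in
        ]
        gm = pd.concat(frames, ignore_index=True)
        report.tables["graph_metrics"] = gm
        report.checksums["graph_metrics"] = io.save_table(gm, out / "graph_metrics.tsv")
        metrics_wide = gm.pivot_table(
            index="subject_id", columns=["metric", "threshold"], values="value"
        ).loc[demo_in["subject_id"]]

    fc_wide = None
    if stages & {"netfc", "infer", "mediate"} and conns:
        fc_wide = netfc.cohort_network_fc(conns, parc).loc[demo_in["subject_id"]]
        fc_long = fc_wide.reset_index().melt(
            id_vars="subject_id", var_name="cell", value_name="value"
        )
        report.tables["network_fc"] = fc_long
        report.checksums["network_fc"] = io.save_table(fc_long, out / "network_fc.tsv")

    # --- inference -------------------------------------------------------
    if "infer" in stages:
        if eta_wide is not None:
            t1 = _similarity_inference(eta_wide, age, sex, ace, cfg.fdr_q)
            report.tables["similarity_correlations"] = t1
            report.checksums["similarity_correlations"] = io.save_table(
                t1, out / "similarity_correlations.tsv"
            )
        if metrics_wide is not None:
            t3 = _graph_inference(metrics_wide, age, sex, ace, cfg.fdr_q)
            report.tables["graph_correlations"] = t3
            report.checksums["graph_correlations"] = io.save_table(
                t3, out / "graph_correlations.tsv"
            )
        if fc_wide is not None:
            t4 = _netfc_inference(fc_wide, age, sex, ace, cfg.fdr_q)
            report.tables["network_fc_correlations"] = t4
            report.checksums["network_fc_correlations"] = io.save_table(
                t4, out / "network_fc_correlations.tsv"
            )
            sig = t4[t4["variable"] == "age"].set_index("cell")
            edges = netfc.edge_list(
                sig["r"], sig["p"], sig["fdr_significant"]
            )
            report.tables["age_edges"] = edges
            report.checksums["age_edges"] = io.save_table(edges, out / "age_edges.tsv")

    # --- mediation -------------------------------------------------------
    if "mediate" in stages:
        candidates: dict[str, np.ndarray] = {}
        if eta_wide is not None:
            for col in eta_wide.columns:
                candidates[f"eta:{col}"] = eta_wide[col].to_numpy()
        if fc_wide is not None:
            for col in fc_wide.columns:
                candidates[f"fc:{col}"] = fc_wide[col].to_numpy()
        med_rows = []
        for name, vals in candidates.items():
            p_age = inference.partial_correlation(vals, age, covariates=sex).p
            p_ace = inference.partial_correlation(
                vals, ace, covariates=np.column_stack([age, sex])
            ).p
            if p_age >= 0.05 or p_ace >= 0.05:
                continue
            res = inference.bootstrap_mediation(
                age, vals, ace, covariates=sex, n_boot=cfg.n_boot, seed=cfg.seed
            )
            row = {"measure": name}
            for path in inference.PATHS:
                row[path] = getattr(res, path)
                row[f"z_{path}"] = res.z_per_path[path]
                row[f"p_{path}"] = res.p_per_path[path]
            med_rows.append(row)
        med_df = pd.DataFrame(med_rows)
        report.tables["mediation"] = med_df
        report.checksums["mediation"] = io.save_table(med_df, out / "mediation.tsv")

    _finish(report, cfg)
    return report


def _partial_rows(wide, age, sex, ace, label_col):
    """Partial correlations of each column with age, sex and ACE-R.

    Age and ACE-R correlations control the other two variables; the sex
    correlation controls age and ACE-R.
    """
    rows = []
    controls = {
        "age": np.column_stack([sex, ace]),
        "sex": np.column_stack([age, ace]),
        "ace_r_total": np.column_stack([age, sex]),
    }
    targets = {"age": age, "sex": sex, "ace_r_total": ace}
    for col in wide.columns:
        v = np.asarray(wide[col], dtype=float)
        ok = np.isfinite(v)
        for var, tgt in targets.items():
            res = inference.partial_correlation(
                v[ok], tgt[ok], covariates=controls[var][ok]
            )
            rows.append(
                {
                    label_col: col,
                    "variable": var,
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)


def _flag_fdr(df: pd.DataFrame, q: float, family_cols=("variable",)) -> pd.DataFrame:
    df = df.copy()
    df["fdr_significant"] = False
    for _, idx in df.groupby(list(family_cols)).groups.items():
        df.loc[idx, "fdr_significant"] = inference.bh_fdr(df.loc[idx, "p"].to_numpy(), q)
    return df


def _similarity_inference(eta_wide, age, sex, ace, q):
    df = _partial_rows(eta_wide, age, sex, ace, "rsn_label")
    return _flag_fdr(df, q)


def _graph_inference(metrics_wide, age, sex, ace, q):
    rows = []
    for (metric, thr) in metrics_wide.columns:
        v = metrics_wide[(metric, thr)].to_numpy(dtype=float)
        ok = np.isfinite(v)
        if ok.sum() < 8 or np.nanstd(v[ok]) == 0:
            continue
        res = inference.partial_correlation(
            v[ok], age[ok], covariates=np.column_stack([sex, ace])[ok]
        )
        plain = inference.partial_correlation(v[ok], ace[ok])
        rows.append(
            {
                "metric": metric,
                "threshold": thr,
                "r_age": res.r,
                "p_age": res.p,
                "r_ace": plain.r,
                "p_ace": plain.p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        for col in ("age", "ace"):
            df[f"fdr_significant_{col}"] = False
            for thr, idx in df.groupby("threshold").groups.items():
                df.loc[idx, f"fdr_significant_{col}"] = inference.bh_fdr(
                    df.loc[idx, f"p_{col}"].to_numpy(), q
                )
    return df


def _netfc_inference(fc_wide, age, sex, ace, q):
    df = _partial_rows(fc_wide, age, sex, ace, "cell")
    return _flag_fdr(df, q)


def _finish(report: RunReport, cfg: RunConfig) -> None:
    meta = {
        "config": io._plain(asdict(cfg)),
        "checksums": report.checksums,
        "conventions": {
            "eta_squared_mask": "all voxels of the shared grid",
            "path_length": "mean over reachable ordered pairs; unreachable count reported",
            "betweenness": "fraction of geodesics per source-target pair (star centre = 1)",
            "threshold": "strict r > threshold on positive correlations",
            "fdr_families": "per table and per variable (similarity: RSNs; "
            "graph: metrics within threshold; network FC: 14 WNFC + 91 BNFC cells)",
        },
    }
    meta.update(report.meta)
    io.save_provenance(meta, report.out_dir / "provenance.yaml")
    report.meta = meta


def parcellation_report(parc: Parcellation | None = None) -> dict:
    """Count-validation report for a parcellation (default fixture if None)."""
    return validate_parcellation(parc if parc is not None else default_parcellation())
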