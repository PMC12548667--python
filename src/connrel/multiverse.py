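"""Orchestration of the pipeline-variant x atlas reliability multiverse.

Runs every configured (pipeline variant, parcellation) cell over a stored
two-session cohort: post-process both sessions per subject, build Fisher-z
connectomes, compute all graph metrics, and estimate ICC(3,1) per
(group, atlas, variant, metric, network) cell.  Emits paper-style report
tables: the metric-reliability grid, per-network reliability with the
network-size correlation, the variant comparison, scrubbing accounting,
negative-edge fractions with/without GSR, group contrasts, and edge-wise
reliability bin proportions — all as TSV/JSON with a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortSpec,
    Parcellation,
    fixture_atlases,
    simulate_cohort,
)
from .connectome import (
    Connectome,
    apply_coverage_rule,
    censor_negatives,
    correlate,
    fisher_z,
    negative_edge_fraction,
)
from .graph import compute_all
from .io import read_cohort, read_parcellation, write_cohort
from .postproc import get_variant, run_pipeline
from .reliability import (
    compare_groups,
    edgewise_icc,
    metric_reliability_table,
    size_reliability_correlation,
    summarize_across_atlases,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class MultiverseConfig:
    cohort_path: str
    parcellations: list[str]
    variants: list[str] = field(
        default_factory=lambda: [
            "primary", "no-gsr", "scrub-2.0", "scrub-1.0", "scrub-0.5",
        ]
    )
    tau: float = 0.10
    seed: int = 0
    output_dir: str = "multiverse_out"
    #: atlas used for edge-wise reliability maps (default: first parcellation)
    edgewise_atlas: str | None = None

    def __post_init__(self) -> None:
        if not self.variants or not self.parcellations:
            raise ValueError("need at least one variant and one parcellation")
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("variant names must be unique")
        for v in self.variants:
            get_variant(v)  # validates

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MultiverseConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class MultiverseTable:
    """All multiverse outputs, long format."""

    reliability: pd.DataFrame      # one row per grid cell (NA rows kept)
    metric_summary: pd.DataFrame   # mean / min-max across atlases
    network_reliability: pd.DataFrame
    scrubbing: pd.DataFrame
    negative_edges: pd.DataFrame
    group_comparison: pd.DataFrame
    edge_bins: pd.DataFrame
    exclusions: pd.DataFrame
    size_correlation: dict
    raw_metrics: pd.DataFrame
    #: per-group edge-wise ICC matrices (labeled, NaN off support)
    edge_icc: dict[str, pd.DataFrame] = field(default_factory=dict)


def _connectome_from_cleaned(
    signals: np.ndarray, parcellation: Parcellation, **prov
) -> tuple[Connectome, float]:
    """Build the censored connectome and the pre-censor negative fraction."""
    r = correlate(signals)
    r = apply_coverage_rule(r, parcellation)
    neg = negative_edge_fraction(r)
    z = fisher_z(censor_negatives(r))
    return (
        Connectome(z=z, node_ids=parcellation.node_ids,
                   atlas_name=parcellation.atlas_name, **prov),
        neg,
    )


def run_multiverse(config: MultiverseConfig) -> MultiverseTable:
    """Evaluate the full variant x atlas grid over the stored cohort."""
    metric_frames: list[pd.DataFrame] = []
    scrub_rows: list[dict] = []
    neg_rows: list[dict] = []
    exclusion_rows: list[dict] = []
    edge_stacks: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    edge_node_ids: tuple[str, ...] = ()
    edgewise_atlas = config.edgewise_atlas
    network_sizes: dict[tuple[str, str], int] = {}

    for parc_path in config.parcellations:
        parc = read_parcellation(parc_path)
        for net, size in parc.network_sizes.items():
            network_sizes[(parc.atlas_name, net)] = size
        cohort_dir = Path(parc_path).parent
        runs = read_cohort(cohort_dir)
        if edgewise_atlas is None:
            edgewise_atlas = parc.atlas_name
        for vname in config.variants:
            variant = get_variant(vname)
            for run in runs:
                try:
                    cleaned = run_pipeline(run, variant)
                except ValueError as err:
                    logger.warning("excluding %s ses-%d (%s/%s): %s",
                                   run.subject_id, run.session,
                                   parc.atlas_name, vname, err)
                    exclusion_rows.append(
                        {"atlas": parc.atlas_name, "variant": vname,
                         "subject": run.subject_id, "session": run.session,
                         "reason": str(err)}
                    )
                    continue
                conn, neg = _connectome_from_cleaned(
                    cleaned.signals, parc,
                    subject_id=run.subject_id, session=run.session,
                    group=run.group, variant=vname,
                )
                metric_frames.append(compute_all(conn, parc, tau=config.tau))
                scrub_rows.append(
                    {"atlas": parc.atlas_name, "variant": vname,
                     "group": run.group, "subject": run.subject_id,
                     "session": run.session,
                     "n_scrubbed": cleaned.mask.n_scrubbed,
                     "retained_minutes": cleaned.mask.retained_minutes}
                )
                neg_rows.append(
                    {"atlas": parc.atlas_name, "variant": vname,
                     "group": run.group, "subject": run.subject_id,
                     "session": run.session, "negative_edge_fraction": neg}
                )
                if parc.atlas_name == edgewise_atlas and vname == "primary":
                    key = (run.group, run.session)
                    edge_stacks.setdefault(key, {})[run.subject_id] = conn.z
                    edge_node_ids = parc.node_ids

    raw_metrics = (
        pd.concat(metric_frames, ignore_index=True)
        if metric_frames
        else pd.DataFrame(columns=["subject", "session", "group", "atlas",
                                   "variant", "metric", "level", "network",
                                   "value"])
    )
    reliability = metric_reliability_table(raw_metrics)
    reliability = _complete_grid(reliability, raw_metrics, config)
    metric_summary = summarize_across_atlases(reliability.dropna(subset=["icc"]))

    scrub_df = pd.DataFrame(scrub_rows)
    scrubbing = scrubbing_summary(scrub_df) if not scrub_df.empty else scrub_df

    neg_df = pd.DataFrame(neg_rows)
    negative_edges = (
        neg_df.groupby(["variant", "group"], sort=True)["negative_edge_fraction"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "neg_fraction_mean", "std": "neg_fraction_sd"})
        if not neg_df.empty else neg_df
    )

    group_comparison = _group_comparison_table(reliability)
    network_reliability, size_corr = _network_table(reliability, network_sizes)
    edge_bins, edge_icc = _edgewise_results(
        edge_stacks, edgewise_atlas, edge_node_ids
    )

    exclusions = pd.DataFrame(
        exclusion_rows,
        columns=["atlas", "variant", "subject", "session", "reason"],
    )
    return MultiverseTable(
        reliability=reliability,
        metric_summary=metric_summary,
        network_reliability=network_reliability,
        scrubbing=scrubbing,
        negative_edges=negative_edges,
        group_comparison=group_comparison,
        edge_bins=edge_bins,
        exclusions=exclusions,
        size_correlation=size_corr,
        raw_metrics=raw_metrics,
        edge_icc=edge_icc,
    )


def _complete_grid(
    reliability: pd.DataFrame, raw: pd.DataFrame, config: MultiverseConfig
) -> pd.DataFrame:
    """Ensure every configured global-metric cell appears (NA where absent)."""
    if raw.empty:
        return reliability
    groups = sorted(raw["group"].unique())
    atlases = sorted(raw["atlas"].unique())
    global_rows = raw[raw["level"] != "per_network"][["metric", "level"]]
    metrics = global_rows.drop_duplicates()
    expected = [
        {"group": g, "atlas": a, "variant": v, "metric": m.metric,
         "level": m.level, "network": ""}
        for g in groups for a in atlases for v in config.variants
        for m in metrics.itertuples()
    ]
    expected_df = pd.DataFrame(expected)
    keys = ["group", "atlas", "variant", "metric", "level", "network"]
    merged = expected_df.merge(reliability, on=keys, how="left")
    per_net = reliability[reliability["level"] == "per_network"]
    out = pd.concat([merged, per_net], ignore_index=True)
    out["bin"] = out["bin"].fillna("NA")
    return out.sort_values(keys, kind="mergesort").reset_index(drop=True)


def scrubbing_summary(scrub_df: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD volumes scrubbed and retained minutes per group x session x variant.

    Retained minutes already account for the discarded non-steady-state
    volumes (the mask covers the post-discard series only).
    """
    out = (
        scrub_df.groupby(["variant", "group", "session"], sort=True)
        .agg(
            volumes_scrubbed_mean=("n_scrubbed", "mean"),
            volumes_scrubbed_sd=("n_scrubbed", "std"),
            retained_minutes_mean=("retained_minutes", "mean"),
            retained_minutes_sd=("retained_minutes", "std"),
        )
        .reset_index()
    )
    sd_cols = ["volumes_scrubbed_sd", "retained_minutes_sd"]
    out[sd_cols] = out[sd_cols].fillna(0.0)
    return out


def _group_comparison_table(reliability: pd.DataFrame) -> pd.DataFrame:
    """Per metric: pooled-t contrast of the two groups' ICCs across atlases."""
    sub = reliability[
        (reliability["variant"] == "primary")
        & (reliability["level"] != "per_network")
    ].dropna(subset=["icc"])
    groups = sorted(sub["group"].unique())
    rows = []
    if len(groups) == 2:
        ga, gb = groups
        for metric, block in sub.groupby("metric", sort=True):
            a = block.loc[block["group"] == ga, "icc"].to_numpy()
            b = block.loc[block["group"] == gb, "icc"].to_numpy()
            if a.size < 2 or b.size < 2:
                continue
            res = compare_groups(a, b, metric_name=str(metric))
            rows.append(
                {"metric": metric, "t_value": res.t_value, "df": res.df,
                 "p_value": res.p_value, "cohens_d": res.cohens_d,
                 "group_a": ga, "group_b": gb,
                 "icc_mean_a": a.mean(), "icc_mean_b": b.mean()}
            )
    return pd.DataFrame(
        rows, columns=["metric", "t_value", "df", "p_value", "cohens_d",
                       "group_a", "group_b", "icc_mean_a", "icc_mean_b"]
    )


def _network_table(
    reliability: pd.DataFrame, network_sizes: dict[tuple[str, str], int]
) -> tuple[pd.DataFrame, dict]:
    net = reliability[reliability["level"] == "per_network"].copy()
    if net.empty:
        return net, {}
    net["n_nodes"] = [
        network_sizes.get((a, n), np.nan)
        for a, n in zip(net["atlas"], net["network"])
    ]
    primary = net[(net["variant"] == "primary")].dropna(subset=["icc"])
    size_corr: dict = {}
    try:
        r, df, p = size_reliability_correlation(primary)
        size_corr = {"r": r, "df": df, "p": p, "n_pairs": df + 2}
    except ValueError as err:
        logger.info("size-reliability correlation unavailable: %s", err)
    return net, size_corr


def _edgewise_results(
    edge_stacks: dict[tuple[str, int], dict[str, np.ndarray]],
    atlas: str | None,
    node_ids: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    rows = []
    matrices: dict[str, pd.DataFrame] = {}
    groups = sorted({g for g, _ in edge_stacks})
    for group in groups:
        s1 = edge_stacks.get((group, 1), {})
        s2 = edge_stacks.get((group, 2), {})
        subjects = sorted(set(s1) & set(s2))
        if len(subjects) < 3:
            continue
        z1 = np.stack([s1[s] for s in subjects])
        z2 = np.stack([s2[s] for s in subjects])
        icc, _, _, bins = edgewise_icc(z1, z2)
        n = icc.shape[0]
        labels = list(node_ids) if len(node_ids) == n else [
            f"n{i + 1}" for i in range(n)
        ]
        matrices[group] = pd.DataFrame(icc, index=labels, columns=labels)
        bins.insert(0, "group", group)
        bins.insert(1, "atlas", atlas or "")
        rows.append(bins)
    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["group", "atlas", "poor", "fair", "good",
                                   "excellent", "n_edges", "n_excluded"])
    )
    return table, matrices


# --------------------------------------------------------------------------- #
# reporting and cohort materialization
# --------------------------------------------------------------------------- #


def report(
    table: MultiverseTable, config: MultiverseConfig, output_dir: str | Path
) -> dict[str, Path]:
    """Write all report tables + manifest; byte-stable under fixed inputs."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "metric_reliability.tsv": table.reliability,
        "metric_summary.tsv": table.metric_summary,
        "network_reliability.tsv": table.network_reliability,
        "variant_scrubbing.tsv": table.scrubbing,
        "negative_edges.tsv": table.negative_edges,
        "group_comparison.tsv": table.group_comparison,
        "edge_bins.tsv": table.edge_bins,
        "exclusions.tsv": table.exclusions,
    }
    written: dict[str, Path] = {}
    for name, df in files.items():
        path = out / name
        df.to_csv(path, sep="\t", index=False, na_rep="NA",
                  float_format=_FLOAT_FMT)
        written[name] = path
    for group, matrix in sorted(table.edge_icc.items()):
        path = out / f"edge_icc_{group}.tsv"
        matrix.to_csv(path, sep="\t", na_rep="NaN", float_format=_FLOAT_FMT)
        written[path.name] = path
    summary = {
        "size_reliability_correlation": table.size_correlation,
        "edge_bin_proportions": table.edge_bins.to_dict(orient="records"),
        "n_reliability_cells": int(len(table.reliability)),
        "n_exclusions": int(len(table.exclusions)),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest = {
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "package_version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest.json"] = out / "manifest.json"
    written["summary.json"] = out / "summary.json"
    return written


def materialize_cohort(
    spec: CohortSpec,
    out_dir: str | Path,
    atlases: list[Parcellation] | None = None,
) -> list[Path]:
    """Simulate and write one cohort per atlas under ``out_dir``.

    Each atlas gets an independently seeded cohort (child seeds derived from
    ``spec.seed``); returns the parcellation paths usable as
    ``MultiverseConfig.parcellations``.
    """
    atlases = atlases or fixture_atlases()
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(len(atlases))
    paths = []
    for parc, child in zip(atlases, child_seeds):
        sub_spec = CohortSpec(**{**asdict(spec),
                                 "seed": int(child % (2**31 - 1)),
                                 "n_nodes": None, "network_sizes": None})
        runs, _ = simulate_cohort(sub_spec, parc, store_latents=False)
        atlas_dir = Path(out_dir) / parc.atlas_name
        write_cohort(runs, parc, atlas_dir)
        paths.append(atlas_dir / "parcellation.tsv")
    return paths
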