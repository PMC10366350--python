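"""End-to-end pipeline: simulate/load -> annotate -> heterogeneity ->
proximity -> communicate -> differential, with a machine-readable manifest.

The pipeline is deterministic given its configuration: permutation seeds
are mandatory and per-sample seeds derive from them by fixed arithmetic,
so re-running a configuration reproduces every output table byte for
byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io_formats
from .communication import spatial_lr_test
from .deconv_metrics import (
    compare_heterogeneity,
    heterogeneity_profile,
    page_scores,
)
from .errors import SpatproxError
from .group_stats import (
    assemble_pi,
    deg_direction_summary,
    differential_pi,
    wilcoxon_markers,
)
from .io_formats import SpatialSample, log_normalize
from .proximity import build_network, proximity_enrichment
from .synthdata import SimulationConfig, StudyBundle, simulate_cohort, write_bundle

log = logging.getLogger("spatprox")

STAGES = (
    "simulate",
    "annotate",
    "heterogeneity",
    "proximity",
    "communicate",
    "differential",
)


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``simulate = True`` (a synthetic cohort is generated from
    ``simulation`` and written under the output directory) or
    ``data_dir`` points at an existing cohort in the on-disk layout of
    :func:`spatprox.synthdata.write_bundle`.
    """

    out_dir: str = "spatprox_run"
    simulate: bool = True
    data_dir: str | None = None
    simulation: dict = field(default_factory=dict)
    # stage parameters
    network_method: str = "delaunay"
    knn_k: int = 6
    prune_factor: float = 4.0
    n_perm: int = 500
    min_cells: int = 4
    epsilon: float = 0.01
    contrib_threshold: float = 0.01
    hetero_cutoff: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise SpatproxError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def _load_bundle(data_dir: Path) -> StudyBundle:
    """Read a cohort from the write_bundle on-disk layout."""
    from .synthdata import StudyBundle, SyntheticTruth

    sheet = io_formats.read_sample_sheet(data_dir / "sample_sheet.tsv")
    samples, deconv = [], {}
    for sid, group in sheet.itertuples(index=False):
        sdir = data_dir / sid
        samples.append(
            io_formats.read_sample(
                sdir / "matrix.mtx",
                sdir / "features.tsv",
                sdir / "barcodes.tsv",
                sdir / "positions.csv",
                sid,
                group,
            )
        )
        deconv[sid] = io_formats.read_deconv(sdir / "deconvolution.tsv")
    # signatures and the L-R catalogue are read lazily by their stages so a
    # missing file aborts with the right stage name
    truth = SyntheticTruth({}, [], [], {})
    return StudyBundle(samples, deconv, truth, sheet, {}, [])


def _spot_labels(scores: pd.DataFrame) -> pd.Series:
    """Dominant deconvolved type per spot (argmax prediction score)."""
    return scores.idxmax(axis=1)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage, writing per-stage TSVs, a manifest and a summary.

    Returns the output directory. Any stage failure is re-raised as a
    :class:`SpatproxError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    stage = "simulate"
    try:
        if config.simulate:
            sim_cfg = SimulationConfig(
                **{"seed": config.seed, **config.simulation}
            )
            log.info("simulate: generating cohort (seed=%d)", sim_cfg.seed)
            bundle = simulate_cohort(sim_cfg)
            write_bundle(bundle, out / "data")
        else:
            if config.data_dir is None:
                raise SpatproxError("data_dir required when simulate is false")
            log.info("simulate: skipped, loading %s", config.data_dir)
            bundle = _load_bundle(Path(config.data_dir))
        (out / "simulate.done.tsv").write_text(
            bundle.sample_sheet.to_csv(sep="\t", index=False), encoding="utf-8"
        )

        stage = "annotate"
        if not bundle.signatures:
            bundle.signatures = io_formats.read_signatures(
                Path(config.data_dir) / "signatures.gmt"
            )
        annot_rows = []
        for sample in bundle.samples:
            page = page_scores(sample, bundle.signatures)
            io_formats.write_table(
                page.reset_index(names="spot_id").assign(
                    sample_id=sample.sample_id
                ),
                out / f"annotate_page_{sample.sample_id}.tsv",
            )
            annot_rows.append(
                pd.DataFrame(
                    {
                        "sample_id": sample.sample_id,
                        "spot_id": page.index,
                        "page_type": page.idxmax(axis=1),
                        "deconv_type": _spot_labels(
                            bundle.deconv[sample.sample_id]
                        ),
                    }
                )
            )
        annotations = pd.concat(annot_rows, ignore_index=True)
        io_formats.write_table(annotations, out / "annotate.tsv")
        log.info("annotate: %d spots annotated", len(annotations))

        stage = "heterogeneity"
        profiles = {}
        spot_rows = []
        for sample in bundle.samples:
            prof = heterogeneity_profile(
                bundle.deconv[sample.sample_id],
                threshold=config.contrib_threshold,
                cutoff=config.hetero_cutoff,
            )
            profiles[sample.sample_id] = prof
            spot_rows.append(
                pd.DataFrame(
                    {
                        "sample_id": sample.sample_id,
                        "spot_id": prof["counts"].index,
                        "n_contributing": prof["counts"].to_numpy(),
                        "shannon": prof["shannon"].to_numpy(),
                    }
                )
            )
        io_formats.write_table(
            pd.concat(spot_rows, ignore_index=True),
            out / "heterogeneity_spots.tsv",
        )
        per_sample = pd.DataFrame(
            {
                "sample_id": sid,
                "fraction_high": prof["fraction_high"],
                "mean_shannon": prof["mean_shannon"],
            }
            for sid, prof in profiles.items()
        )
        io_formats.write_table(per_sample, out / "heterogeneity_samples.tsv")
        het_tests = compare_heterogeneity(profiles, bundle.sample_sheet)
        io_formats.write_table(het_tests, out / "heterogeneity_tests.tsv")
        log.info("heterogeneity: %s", per_sample.to_dict("records"))

        stage = "proximity"
        networks = {}
        prox_results = []
        for i, sample in enumerate(bundle.samples):
            coords = pd.DataFrame(
                {
                    "spot_id": sample.spot_ids,
                    "x": sample.coords[:, 0],
                    "y": sample.coords[:, 1],
                }
            )
            net = build_network(
                coords,
                method=config.network_method,
                k=config.knn_k,
                prune_factor=config.prune_factor,
            )
            networks[sample.sample_id] = net
            labels = _spot_labels(bundle.deconv[sample.sample_id]).to_numpy()
            res = proximity_enrichment(
                net,
                labels,
                n_perm=config.n_perm,
                seed=config.seed + 1000 + i,
                sample_id=sample.sample_id,
            )
            prox_results.append(res)
            log.info(
                "proximity: %s done (%d pairs)", sample.sample_id, len(res)
            )
        prox_all = pd.concat(prox_results, ignore_index=True)
        io_formats.write_table(prox_all, out / "proximity.tsv")

        stage = "communicate"
        if not bundle.lr_catalog:
            if config.data_dir is None:
                raise SpatproxError("empty ligand-receptor catalogue")
            bundle.lr_catalog = io_formats.read_lr(
                Path(config.data_dir) / "lr_catalog.tsv"
            )
        comm_results = []
        for i, sample in enumerate(bundle.samples):
            labels = _spot_labels(bundle.deconv[sample.sample_id]).to_numpy()
            res = spatial_lr_test(
                sample,
                networks[sample.sample_id],
                labels,
                bundle.lr_catalog,
                n_perm=config.n_perm,
                min_cells=config.min_cells,
                epsilon=config.epsilon,
                seed=config.seed + 2000 + i,
            )
            comm_results.append(res)
            log.info(
                "communicate: %s done (%d rows, %d significant)",
                sample.sample_id,
                len(res),
                int(res["significant"].sum()),
            )
        comm_all = pd.concat(comm_results, ignore_index=True)
        io_formats.write_table(comm_all, out / "communicate.tsv")

        stage = "differential"
        diffs = {}
        for name, results in (
            ("proximity", prox_results),
            ("communication", comm_results),
        ):
            table = assemble_pi(results, bundle.sample_sheet)
            diff = differential_pi(table, bundle.sample_sheet)
            diff = diff.merge(
                table["n_imputed"].rename("n_imputed"),
                left_on="unit",
                right_index=True,
            )
            diffs[name] = diff
            io_formats.write_table(diff, out / f"differential_{name}.tsv")
        _write_summary(out / "summary.txt", per_sample, het_tests, diffs)
        _write_manifest(out / "manifest.json", config)
        log.info("pipeline complete: %s", out)
        return out
    except SpatproxError:
        log.error("stage %s failed", stage)
        raise
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise SpatproxError(f"stage {stage!r} failed: {exc}") from exc


def run_markers(
    config: RunConfig, bundle: StudyBundle | None = None
) -> pd.DataFrame:
    """Primary-vs-recurrent marker genes per dominant cell type (pooled spots).

    For each cell type, spots of that dominant type are pooled across
    samples and the two groups contrasted by Wilcoxon rank-sum on
    log-normalised expression. Writes per-type DEG tables and an
    UpSet-style direction summary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        if config.simulate:
            bundle = simulate_cohort(
                SimulationConfig(**{"seed": config.seed, **config.simulation})
            )
        else:
            bundle = _load_bundle(Path(config.data_dir))
    gene_ids = bundle.samples[0].gene_ids
    mats, groups, types = [], [], []
    for sample in bundle.samples:
        X = log_normalize(sample)
        mats.append(np.asarray(X.todense()))
        groups.extend([sample.group] * sample.n_spots)
        types.extend(_spot_labels(bundle.deconv[sample.sample_id]).tolist())
    X = np.concatenate(mats, axis=1)
    groups = np.asarray(groups)
    types = np.asarray(types)

    tables = []
    for t in sorted(set(types)):
        mask = types == t
        if (groups[mask] == "primary").sum() < 3:
            continue
        if (groups[mask] == "recurrent").sum() < 3:
            continue
        tab = wilcoxon_markers(
            X[:, mask],
            groups[mask],
            ("recurrent", "primary"),
            gene_ids=gene_ids,
        )
        tab.insert(0, "cell_type", t)
        tables.append(tab)
    if not tables:
        raise SpatproxError("no cell type has >= 3 spots in both groups")
    all_tabs = pd.concat(tables, ignore_index=True)
    io_formats.write_table(all_tabs, out / "markers.tsv")
    summary = deg_direction_summary(tables)
    (out / "markers_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"
    )
    return all_tabs


def _write_summary(path: Path, per_sample, het_tests, diffs) -> None:
    lines = ["spatprox run summary", "====================", ""]
    lines.append("Per-sample heterogeneity:")
    for row in per_sample.itertuples(index=False):
        lines.append(
            f"  {row.sample_id}: fraction >cutoff types = "
            f"{row.fraction_high:.4f}, mean Shannon = {row.mean_shannon:.4f}"
        )
    lines.append("")
    for row in het_tests.itertuples(index=False):
        lines.append(
            f"Heterogeneity test [{row.metric}, {row.level}]: "
            f"stat = {row.statistic:.4g}, p = {row.p_value:.4g}"
        )
    for name, diff in diffs.items():
        sig = diff[diff["significant"]]
        up = sig[sig["direction"] > 0]
        down = sig[sig["direction"] < 0]
        lines.append("")
        lines.append(
            f"Differential {name}: {len(sig)} significant units "
            f"({len(up)} up in recurrent, {len(down)} down)"
        )
        for row in sig.itertuples(index=False):
            arrow = "up" if row.direction > 0 else "down"
            lines.append(
                f"  {row.unit}: t = {row.t:.3f}, p = {row.p_value:.4g} ({arrow})"
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_manifest(path: Path, config: RunConfig) -> None:
    manifest = {
        "package": "spatprox",
        "version": __version__,
        "stages": list(STAGES),
        "parameters": asdict(config),
    }
    path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )


def _setup_logging(logfile: Path) -> None:
    if not log.handlers:
        log.setLevel(logging.INFO)
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("[%(levelname)s] %(message)s"))
        log.addHandler(sh)
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            log.removeHandler(h)
            h.close()
    fh = logging.FileHandler(logfile, mode="w", encoding="utf-8")
    fh.setFormatter(
        logging.Formatter("%(asctime)s [%(levelname)s] %(message)s")
    )
    log.addHandler(fh)
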