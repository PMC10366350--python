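"""Synthetic Visium-like cohort generator with known planted effects.

Each sample is a hex-packed spot grid carrying spatially contiguous
cell-type domains (smoothed Gaussian random fields, argmax per spot),
Dirichlet-distributed deconvolution score rows dominated by the spot's
true type, and negative-binomial counts. Three kinds of group-restricted
effects can be planted, matching the downstream tests:

* heterogeneity — the recurrent arm's Dirichlet concentration is flatter
  than the primary arm's, raising spot entropy and contributing-type
  counts;
* proximity — a fraction ``s`` of one type's spots is relocated into the
  boundary zone of another type's domains, raising their adjacency on the
  neighbour graph;
* communication — the ligand mean is multiplied by a fold-effect in
  sender-type spots adjacent to receiver-type spots (and the receptor
  symmetrically), creating interface-restricted co-elevation.

Everything is deterministic given the configuration seed; the planted
truth is recorded separately and never consumed by the analysis stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.spatial

from . import io_formats
from .communication import interface_sets
from .errors import InvalidParameterError
from .io_formats import SpatialSample
from .proximity import build_network

_ROW_STEP = 1.0  # row pitch per unit spacing (offset rows, hex-like packing)


def _type_name(i: int) -> str:
    return f"T{i}"


def default_lr_catalog(n_pairs: int = 8) -> list[tuple[str, str]]:
    """Catalogue over the reserved low-index genes: (G0000, G0001), ..."""
    return [
        (f"G{2 * i:04d}", f"G{2 * i + 1:04d}") for i in range(n_pairs)
    ]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a desk-scale version of a six-section bladder-tumour
    cohort: three primary and three recurrent samples, hex grids of
    ~2,000 spots (the real sections carry 3,500-4,600), seven cell types
    with 2-7 of them contributing >1% score per spot, and recurrent-arm
    planted effects in heterogeneity (flatter Dirichlet), proximity
    (T0-T1 mixing) and interface-restricted L-R co-expression.
    """

    n_primary: int = 3
    n_recurrent: int = 3
    grid_rows: int = 45
    grid_cols: int = 45
    spot_spacing: float = 1.0
    jitter_sd: float = 0.05
    n_types: int = 7
    n_genes: int = 120
    domain_scale: float = 3.0
    dirichlet_alpha_primary: tuple[float, ...] | None = None
    dirichlet_alpha_recurrent: tuple[float, ...] | None = None
    dominance: float = 5.0
    planted_proximity: list[tuple[int, int, float, str]] = field(
        default_factory=lambda: [(0, 1, 0.8, "recurrent")]
    )
    lr_catalog: list[tuple[str, str]] = field(default_factory=default_lr_catalog)
    planted_lr: list[tuple[int, int, str, str, float, str]] = field(
        default_factory=lambda: [(0, 1, "G0000", "G0001", 3.0, "recurrent")]
    )
    nb_mean: float = 1.0
    nb_dispersion: float = 2.0
    n_marker_genes: int = 8
    marker_fold: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        # coerce YAML-style nested lists to tuples
        self.lr_catalog = [tuple(p) for p in self.lr_catalog]
        self.planted_proximity = [tuple(p) for p in self.planted_proximity]
        self.planted_lr = [tuple(p) for p in self.planted_lr]
        if self.dirichlet_alpha_primary is None:
            self.dirichlet_alpha_primary = tuple([0.40] * self.n_types)
        if self.dirichlet_alpha_recurrent is None:
            self.dirichlet_alpha_recurrent = tuple([0.53] * self.n_types)
        self.validate()

    def validate(self) -> None:
        if self.grid_rows * self.grid_cols < 16:
            raise InvalidParameterError("grid must have at least 16 spots")
        if self.spot_spacing <= 0:
            raise InvalidParameterError("spot_spacing must be positive")
        for name in ("dirichlet_alpha_primary", "dirichlet_alpha_recurrent"):
            alpha = np.asarray(getattr(self, name), dtype=float)
            if len(alpha) != self.n_types or (alpha <= 0).any():
                raise InvalidParameterError(
                    f"{name} must be strictly positive with length n_types"
                )
        for a, b, s, group in self.planted_proximity:
            if not (0 <= a < self.n_types and 0 <= b < self.n_types):
                raise InvalidParameterError(
                    f"planted proximity type index out of range: ({a}, {b})"
                )
            if not 0.0 <= s <= 1.0:
                raise InvalidParameterError("mixing strength must lie in [0, 1]")
            if group not in io_formats.GROUPS:
                raise InvalidParameterError(f"unknown group {group!r}")
        cat = set(self.lr_catalog)
        genes = {f"G{i:04d}" for i in range(self.n_genes)}
        for snd, rcv, lig, rec, e, group in self.planted_lr:
            if not (0 <= snd < self.n_types and 0 <= rcv < self.n_types):
                raise InvalidParameterError("planted L-R type index out of range")
            if (lig, rec) not in cat:
                raise InvalidParameterError(
                    f"planted pair ({lig}, {rec}) absent from catalogue"
                )
            if lig not in genes or rec not in genes:
                raise InvalidParameterError(
                    f"planted genes ({lig}, {rec}) outside the gene universe"
                )
            if e <= 0:
                raise InvalidParameterError("fold-effect must be positive")
            if group not in io_formats.GROUPS:
                raise InvalidParameterError(f"unknown group {group!r}")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def type_names(self) -> list[str]:
        return [_type_name(i) for i in range(self.n_types)]

    def marker_sets(self) -> dict[str, list[str]]:
        """Per-type marker genes, drawn after the reserved catalogue genes."""
        start = 2 * len(self.lr_catalog)
        needed = start + self.n_types * self.n_marker_genes
        if needed > self.n_genes:
            raise InvalidParameterError(
                f"n_genes={self.n_genes} too small for catalogue plus "
                f"{self.n_types} x {self.n_marker_genes} marker genes "
                f"(need {needed})"
            )
        return {
            _type_name(t): [
                f"G{start + t * self.n_marker_genes + j:04d}"
                for j in range(self.n_marker_genes)
            ]
            for t in range(self.n_types)
        }


@dataclass
class SyntheticTruth:
    """Ground truth: per-sample spot labels and the realised planted effects."""

    labels: dict[str, pd.Series]
    planted_proximity: list[dict]
    planted_lr: list[dict]
    lr_interfaces: dict[tuple[str, int], tuple[list[str], list[str]]]


@dataclass
class StudyBundle:
    """One synthetic cohort: samples, scores, truth and the sample sheet."""

    samples: list[SpatialSample]
    deconv: dict[str, pd.DataFrame]
    truth: SyntheticTruth
    sample_sheet: pd.DataFrame
    signatures: dict[str, list[str]]
    lr_catalog: list[tuple[str, str]]


# ---------------------------------------------------------------------------
# generators


def make_grid(
    grid_rows: int,
    grid_cols: int,
    spacing: float,
    jitter_sd: float = 0.0,
    seed: int | Sequence[int] = 0,
) -> pd.DataFrame:
    """Hex-packed spot grid with optional Gaussian positional jitter.

    Odd rows are offset by half a spacing in x (hex-like packing); the
    row pitch equals the spacing, so within-row neighbours sit at distance
    ``spacing``. Returns a frame with ``spot_id``, ``x``, ``y``.
    """
    if grid_rows < 2 or grid_cols < 2:
        raise InvalidParameterError("grid_rows and grid_cols must be >= 2")
    if spacing <= 0:
        raise InvalidParameterError("spacing must be positive")
    if jitter_sd < 0:
        raise InvalidParameterError("jitter_sd must be >= 0")
    rows, cols = np.mgrid[0:grid_rows, 0:grid_cols]
    rows, cols = rows.ravel(), cols.ravel()
    x = cols * spacing + (rows % 2) * spacing / 2.0
    y = rows * spacing * _ROW_STEP
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, jitter_sd, size=len(x))
        y = y + rng.normal(0.0, jitter_sd, size=len(y))
    ids = [f"spot_{r:03d}_{c:03d}" for r, c in zip(rows, cols)]
    return pd.DataFrame({"spot_id": ids, "x": x, "y": y})


def simulate_labels(
    coords: pd.DataFrame,
    n_types: int,
    domain_scale: float,
    planted_proximity: Sequence[tuple[int, int, float]] = (),
    seed: int | Sequence[int] = 0,
) -> np.ndarray:
    """Spatially contiguous type labels with optional planted mixing.

    One latent field per type is built by Gaussian-kernel smoothing of iid
    normals (bandwidth ``domain_scale``); each spot takes the argmax type,
    which yields contiguous domains of diameter ~``domain_scale``. For
    each planted ``(a, b, s)``, a fraction ``s`` of type-b spots swaps
    labels with spots on the rim of the type-a domains (a-labelled spots
    touching another type), relocating b into the a boundary zone and
    scattering displaced a labels into b territory — both of which raise
    a-b adjacency — while preserving the label multiset. ``s = 0`` leaves
    the baseline field untouched.

    Returns integer labels in ``[0, n_types)``.
    """
    if n_types < 1:
        raise InvalidParameterError("n_types must be >= 1")
    if domain_scale <= 0:
        raise InvalidParameterError("domain_scale must be positive")
    xy = coords[["x", "y"]].to_numpy(dtype=float)
    n = len(xy)

    ss = np.random.SeedSequence(seed)
    field_ss, plant_ss = ss.spawn(2)

    if n_types == 1:
        labels = np.zeros(n, dtype=np.int64)
    else:
        rng = np.random.default_rng(field_ss)
        D2 = scipy.spatial.distance.cdist(xy, xy, "sqeuclidean")
        W = np.exp(-D2 / (2.0 * domain_scale**2))
        Z = rng.standard_normal((n, n_types))
        labels = np.argmax(W @ Z, axis=1).astype(np.int64)

    active = [(a, b, s) for a, b, s in _as_triples(planted_proximity) if s > 0]
    for a, b, s in _as_triples(planted_proximity):
        if not (0 <= a < n_types and 0 <= b < n_types):
            raise InvalidParameterError(
                f"planted type index out of range: ({a}, {b})"
            )
        if not 0.0 <= s <= 1.0:
            raise InvalidParameterError("mixing strength must lie in [0, 1]")
    if active and n >= 3:
        rng = np.random.default_rng(plant_ss)
        net = build_network(coords, method="delaunay")
        nbrs = net.neighbor_lists()
        for a, b, s in active:
            near_other = np.array(
                [any(labels[j] != a for j in nbrs[i]) for i in range(n)]
            )
            # rim of the a-domains: a-labelled spots touching the outside
            candidates = np.flatnonzero((labels == a) & near_other)
            movable = np.flatnonzero(labels == b)
            n_move = min(
                int(round(s * len(movable))), len(candidates), len(movable)
            )
            if n_move == 0:
                continue
            src = rng.choice(movable, size=n_move, replace=False)
            dst = rng.choice(candidates, size=n_move, replace=False)
            labels[src], labels[dst] = labels[dst].copy(), b
    return labels


def _as_triples(planted) -> list[tuple[int, int, float]]:
    out = []
    for entry in planted:
        if len(entry) == 3:
            out.append((int(entry[0]), int(entry[1]), float(entry[2])))
        else:
            raise InvalidParameterError(
                "planted proximity entries must be (type_a, type_b, s)"
            )
    return out


def simulate_deconv(
    labels: np.ndarray,
    alpha: Sequence[float],
    seed: int | Sequence[int] = 0,
    dominance: float = 5.0,
    spot_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Dirichlet deconvolution score rows dominated by the spot's true type.

    Each row is Dirichlet with concentration ``alpha`` whose component at
    the spot's true type is multiplied by ``dominance``; rows sum to one.
    """
    alpha = np.asarray(alpha, dtype=float)
    if (alpha <= 0).any():
        raise InvalidParameterError("alpha must be strictly positive")
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size and labels.max() >= len(alpha):
        raise InvalidParameterError("label index exceeds alpha length")
    if dominance <= 0:
        raise InvalidParameterError("dominance must be positive")
    rng = np.random.default_rng(seed)
    A = np.tile(alpha, (len(labels), 1))
    A[np.arange(len(labels)), labels] *= dominance
    G = rng.gamma(A)
    rows = G / G.sum(axis=1, keepdims=True)
    idx = list(spot_ids) if spot_ids is not None else list(range(len(labels)))
    return pd.DataFrame(
        rows, index=idx, columns=[_type_name(i) for i in range(len(alpha))]
    )


def simulate_expression(
    labels: np.ndarray,
    network,
    lr_catalog: Sequence[tuple[str, str]],
    planted_lr: Sequence[tuple[int, int, str, str, float]],
    n_genes: int,
    nb_mean: float,
    nb_dispersion: float,
    seed: int | Sequence[int] = 0,
    marker_sets: Mapping[str, Sequence[str]] | None = None,
    marker_fold: float = 3.0,
    gene_ids: Sequence[str] | None = None,
) -> tuple[sp.csr_matrix, list[str], dict[int, tuple[np.ndarray, np.ndarray]]]:
    """Negative-binomial counts with marker structure and planted L-R effects.

    Per-gene baseline means are ``nb_mean`` times a log-normal gene
    factor. Marker genes of a type have their mean multiplied by
    ``marker_fold`` in that type's spots. For each planted
    ``(sender, receiver, ligand, receptor, e)`` the ligand mean is
    multiplied by ``e`` in sender-type spots adjacent to receiver-type
    spots and the receptor mean by ``e`` in the symmetric receiver
    interface; ``e = 1`` is a no-op. Counts are negative binomial with
    dispersion ``nb_dispersion`` (variance ``mu + mu^2 / theta``).

    Returns ``(counts gene x spot CSR, gene ids, {planted index:
    (sender interface indices, receiver interface indices)})``.
    """
    if nb_mean < 0:
        raise InvalidParameterError("nb_mean must be >= 0")
    if nb_dispersion <= 0:
        raise InvalidParameterError("nb_dispersion must be positive")
    labels = np.asarray(labels, dtype=np.int64)
    if gene_ids is None:
        gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    gene_ids = list(gene_ids)
    if len(gene_ids) != n_genes:
        raise InvalidParameterError("gene_ids length must equal n_genes")
    gene_idx = {g: i for i, g in enumerate(gene_ids)}
    cat = set((lig, rec) for lig, rec in lr_catalog)

    ss = np.random.SeedSequence(seed)
    gene_ss, count_ss = ss.spawn(2)
    rng_genes = np.random.default_rng(gene_ss)

    factors = rng_genes.lognormal(mean=0.0, sigma=0.5, size=n_genes)
    M = np.outer(nb_mean * factors, np.ones(len(labels)))

    if marker_sets:
        for t_name, genes in marker_sets.items():
            t = int(str(t_name).lstrip("T"))
            in_type = labels == t
            for g in genes:
                if g in gene_idx:
                    M[gene_idx[g], in_type] *= marker_fold

    interfaces: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k, (snd, rcv, lig, rec, e) in enumerate(planted_lr):
        if (lig, rec) not in cat:
            raise InvalidParameterError(
                f"planted pair ({lig}, {rec}) absent from catalogue"
            )
        if lig not in gene_idx or rec not in gene_idx:
            raise InvalidParameterError(
                f"planted genes ({lig}, {rec}) outside the gene universe"
            )
        send_iface, recv_iface = interface_sets(network, labels, snd, rcv)
        interfaces[k] = (send_iface, recv_iface)
        M[gene_idx[lig], send_iface] *= e
        M[gene_idx[rec], recv_iface] *= e

    rng_counts = np.random.default_rng(count_ss)
    theta = nb_dispersion
    p = theta / (theta + M)
    counts = rng_counts.negative_binomial(theta, p)
    return sp.csr_matrix(counts, dtype=np.int64), gene_ids, interfaces


def simulate_cohort(config: SimulationConfig) -> StudyBundle:
    """Generate a full multi-sample cohort with group-restricted planted effects.

    Per-sample seeds are ``config.seed + sample index``; equal
    configurations produce equal bundles.
    """
    config.validate()
    marker_sets = config.marker_sets()
    samples: list[SpatialSample] = []
    deconv: dict[str, pd.DataFrame] = {}
    labels_by_sample: dict[str, pd.Series] = {}
    lr_interfaces: dict[tuple[str, int], tuple[list[str], list[str]]] = {}
    sheet_rows = []

    groups = ["primary"] * config.n_primary + ["recurrent"] * config.n_recurrent
    per_group_counter = {"primary": 0, "recurrent": 0}
    for i, group in enumerate(groups):
        per_group_counter[group] += 1
        sid = f"{'P' if group == 'primary' else 'R'}{per_group_counter[group]}"
        base = config.seed + i

        coords = make_grid(
            config.grid_rows,
            config.grid_cols,
            config.spot_spacing,
            config.jitter_sd,
            seed=[base, 0],
        )
        planted_prox = [
            (a, b, s)
            for a, b, s, g in config.planted_proximity
            if g == group
        ]
        labels = simulate_labels(
            coords,
            config.n_types,
            config.domain_scale,
            planted_prox,
            seed=[base, 1],
        )
        alpha = (
            config.dirichlet_alpha_primary
            if group == "primary"
            else config.dirichlet_alpha_recurrent
        )
        scores = simulate_deconv(
            labels,
            alpha,
            seed=[base, 2],
            dominance=config.dominance,
            spot_ids=list(coords["spot_id"]),
        )
        network = build_network(coords, method="delaunay")
        planted_lr = [
            (snd, rcv, lig, rec, e)
            for snd, rcv, lig, rec, e, g in config.planted_lr
            if g == group
        ]
        counts, gene_ids, ifaces = simulate_expression(
            labels,
            network,
            config.lr_catalog,
            planted_lr,
            config.n_genes,
            config.nb_mean,
            config.nb_dispersion,
            seed=[base, 3],
            marker_sets=marker_sets,
            marker_fold=config.marker_fold,
        )
        spot_ids = list(coords["spot_id"])
        samples.append(
            SpatialSample(
                sample_id=sid,
                group=group,
                counts=counts,
                gene_ids=gene_ids,
                spot_ids=spot_ids,
                coords=coords[["x", "y"]].to_numpy(),
            )
        )
        deconv[sid] = scores
        labels_by_sample[sid] = pd.Series(
            [_type_name(t) for t in labels], index=spot_ids, name="true_type"
        )
        local_k = 0
        for k, (snd, rcv, lig, rec, e, g) in enumerate(config.planted_lr):
            if g != group:
                continue
            s_ifc, r_ifc = ifaces[local_k]
            lr_interfaces[(sid, k)] = (
                [spot_ids[j] for j in s_ifc],
                [spot_ids[j] for j in r_ifc],
            )
            local_k += 1
        sheet_rows.append({"sample_id": sid, "group": group})

    truth = SyntheticTruth(
        labels=labels_by_sample,
        planted_proximity=[
            {"type_a": _type_name(a), "type_b": _type_name(b), "s": s, "group": g}
            for a, b, s, g in config.planted_proximity
        ],
        planted_lr=[
            {
                "sender": _type_name(snd),
                "receiver": _type_name(rcv),
                "ligand": lig,
                "receptor": rec,
                "effect": e,
                "group": g,
            }
            for snd, rcv, lig, rec, e, g in config.planted_lr
        ],
        lr_interfaces=lr_interfaces,
    )
    return StudyBundle(
        samples=samples,
        deconv=deconv,
        truth=truth,
        sample_sheet=pd.DataFrame(sheet_rows),
        signatures=marker_sets,
        lr_catalog=list(config.lr_catalog),
    )


# ---------------------------------------------------------------------------
# on-disk export in the exact formats the pipeline reads


def write_bundle(bundle: StudyBundle, out_dir: str | Path) -> Path:
    """Write a cohort in the pipeline's input formats.

    Layout: ``<out>/<sample>/{matrix.mtx,features.tsv,barcodes.tsv,
    positions.csv,deconvolution.tsv}``, plus ``sample_sheet.tsv``,
    ``signatures.gmt``, ``lr_catalog.tsv`` and ``truth_labels.tsv`` (the
    truth file is never read by analysis stages).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sample in bundle.samples:
        sdir = out_dir / sample.sample_id
        io_formats.write_sample(sample, sdir)
        io_formats.write_deconv(
            bundle.deconv[sample.sample_id], sdir / "deconvolution.tsv"
        )
    io_formats.write_table(bundle.sample_sheet, out_dir / "sample_sheet.tsv")
    io_formats.write_signatures(bundle.signatures, out_dir / "signatures.gmt")
    io_formats.write_lr(bundle.lr_catalog, out_dir / "lr_catalog.tsv")
    truth_rows = []
    for sid, lab in bundle.truth.labels.items():
        for spot, t in lab.items():
            truth_rows.append({"sample_id": sid, "spot_id": spot, "true_type": t})
    io_formats.write_table(pd.DataFrame(truth_rows), out_dir / "truth_labels.tsv")
    return out_dir
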