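"""Seeded generators with known ground truth.

``simulate_expression`` emulates a multi-sample AD-vs-NDC single-nucleus
cohort: negative-binomial counts over a cell-type mixture, a planted
senescent sub-fraction whose senescence-set genes are scaled by a
fold-change, per-sample amyloid loads that rise linearly with the true
senescent fraction, and donor ages.  ``simulate_imaging`` emulates IMC
ROIs: cells placed uniformly in 500 x 500 um regions, disk plaques with
bounded-retry non-overlap placement, and log-normal channel intensities
with boosted senescence-marker positivity near plaques.

Every draw flows from a single ``numpy`` Generator seeded from the
config, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ExpressionDataset, GeneSetCollection, ImagingCellTable, PlaqueSet

REGIONS = ("EC", "MTG", "SSC")


def _default_mixture() -> dict:
    return {"Micro": 0.2, "Oligo": 0.3, "Astro": 0.2, "Exc": 0.2, "Inh": 0.1}


def _default_pi() -> dict:
    # planted senescent fractions per (diagnosis, cell type); unlisted
    # cell types fall back to the baseline below
    return {("AD", "Micro"): 0.25, ("NDC", "Micro"): 0.05}


@dataclass
class ExpressionSimConfig:
    n_samples_per_arm: int = 8
    cells_per_sample: int = 150
    cell_type_weights: dict = field(default_factory=_default_mixture)
    n_genes: int = 1000
    gene_set_size: int = 40
    pi: dict = field(default_factory=_default_pi)
    baseline_pi: float = 0.02
    fold_change: float = 4.0
    nb_mean_log_mu: float = 0.0    # lognormal grid of gene base means
    nb_mean_log_sd: float = 1.0
    nb_dispersion: float = 0.5
    pi_sample_concentration: float = 30.0  # Beta spread of per-sample pi
    amyloid_alpha: float = 2.0     # % area at pi = 0
    amyloid_beta: float = 60.0     # % area per unit senescent fraction
    amyloid_noise_sd: float = 1.5
    age_range_ndc: tuple = (50, 100)
    age_range_ad: tuple = (60, 95)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.cell_type_weights.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"cell-type mixture weights sum to {total}, not 1")
        for (arm, ct), p in self.pi.items():
            if not 0 <= p <= 1:
                raise ValueError(f"pi[{arm},{ct}] = {p} outside [0, 1]")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be > 0")


def simulate_expression(config: ExpressionSimConfig, seed: int | None = None):
    """Generate (ExpressionDataset, GeneSetCollection, truth table).

    The truth table has one row per cell: cell_id, sample_id, cell_type,
    diagnosis, region, senescent (the planted flag).  Senescent cells
    have their senescence-set gene means multiplied by the fold-change.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    gene_ids = np.array([f"G{i:04d}" for i in range(config.n_genes)], dtype=object)
    set_genes = list(gene_ids[: config.gene_set_size])
    base_mean = rng.lognormal(config.nb_mean_log_mu, config.nb_mean_log_sd, config.n_genes)

    types = list(config.cell_type_weights)
    weights = np.array([config.cell_type_weights[t] for t in types])
    cells_meta = []
    counts_cols = []
    truth_rows = []
    sample_rows = []
    cell_counter = 0
    set_idx = np.arange(config.gene_set_size)
    shape = 1.0 / config.nb_dispersion  # gamma shape for NB mixing

    for arm in ("NDC", "AD"):
        lo, hi = config.age_range_ndc if arm == "NDC" else config.age_range_ad
        for s in range(config.n_samples_per_arm):
            sample_id = f"{arm}{s + 1:02d}"
            region = REGIONS[s % len(REGIONS)]
            age = int(rng.integers(lo, hi + 1))
            sex = "F" if s % 2 else "M"
            ct_draw = rng.choice(len(types), size=config.cells_per_sample, p=weights)
            # per-sample senescent propensity, Beta-spread around the arm mean
            pi_s = {}
            for ct in types:
                p = config.pi.get((arm, ct), config.baseline_pi)
                if 0 < p < 1:
                    kappa = config.pi_sample_concentration
                    pi_s[ct] = rng.beta(p * kappa, (1 - p) * kappa)
                else:
                    pi_s[ct] = p
            n_sen_micro = 0
            n_micro = 0
            for ct_i in ct_draw:
                ct = types[ct_i]
                senescent = bool(rng.random() < pi_s[ct])
                mean = base_mean.copy()
                if senescent:
                    mean[set_idx] *= config.fold_change
                lam = rng.gamma(shape, mean / shape)
                counts = rng.poisson(lam)
                cell_id = f"cell{cell_counter:06d}"
                cell_counter += 1
                counts_cols.append(counts)
                cells_meta.append(
                    {
                        "cell_id": cell_id, "sample_id": sample_id, "cell_type": ct,
                        "diagnosis": arm, "region": region, "age": age, "sex": sex,
                    }
                )
                truth_rows.append(
                    {
                        "cell_id": cell_id, "sample_id": sample_id, "cell_type": ct,
                        "diagnosis": arm, "region": region, "senescent": senescent,
                    }
                )
                if ct == "Micro":
                    n_micro += 1
                    n_sen_micro += senescent
            frac = n_sen_micro / n_micro if n_micro else 0.0
            amyloid = max(
                0.0,
                config.amyloid_alpha + config.amyloid_beta * frac
                + rng.normal(0, config.amyloid_noise_sd),
            )
            sample_rows.append(
                {
                    "sample_id": sample_id, "diagnosis": arm, "region": region,
                    "age": age, "sex": sex, "amyloid_load": amyloid,
                    "true_senescent_fraction_micro": frac,
                }
            )

    matrix = sp.csr_matrix(np.column_stack(counts_cols).astype(float))
    meta = pd.DataFrame(cells_meta).set_index("cell_id")
    sample_meta = pd.DataFrame(sample_rows)
    meta = meta.join(sample_meta.set_index("sample_id")["amyloid_load"], on="sample_id")
    dataset = ExpressionDataset(
        matrix=matrix,
        gene_ids=gene_ids,
        cell_ids=np.array(meta.index, dtype=object),
        cell_meta=meta,
        normalised=False,
    )
    collection = GeneSetCollection(
        sets={"CSP_synthetic": set_genes},
        provenance={"CSP_synthetic": "synthetic senescence gene set (planted signal)"},
    )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["sample_meta"] = sample_meta
    return dataset, collection, truth


# ---------------------------------------------------------------------------
# Imaging simulation
# ---------------------------------------------------------------------------

def _default_baseline_rates() -> dict:
    return {"GLB1": 0.03, "p16": 0.05, "p21": 0.05, "gH2AX": 0.05}


def _default_peri_boost() -> dict:
    return {"GLB1": 0.30, "p16": 0.15}


def _default_imaging_mixture() -> dict:
    return {"Micro": 0.3, "Astro": 0.2, "Oligo": 0.3, "Neuron": 0.2}


CELL_TYPE_MARKER = {"Micro": "Iba1", "Astro": "GFAP", "Oligo": "OLIG2", "Neuron": "MAP2"}


@dataclass
class ImagingSimConfig:
    n_samples: int = 10
    rois_per_sample: int = 4
    roi_size_um: tuple = (500.0, 500.0)
    cells_per_roi: int = 100
    cell_type_weights: dict = field(default_factory=_default_imaging_mixture)
    plaques_per_roi: int = 4
    plaque_radius_um: tuple = (8.0, 20.0)   # uniform range
    baseline_rates: dict = field(default_factory=_default_baseline_rates)
    peri_boost: dict = field(default_factory=_default_peri_boost)
    peri_radius_um: float = 10.0
    intensity_pos_log_mean: float = 2.0
    intensity_neg_log_mean: float = -1.0
    intensity_log_sd: float = 0.4
    max_placement_retries: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.roi_size_um) <= 0:
            raise ValueError("ROI size must be > 0")
        for r in {**self.baseline_rates, **self.peri_boost}.values():
            if not 0 <= r <= 1:
                raise ValueError("positivity rates must lie in [0, 1]")


def _place_plaques(rng, config: ImagingSimConfig) -> list[tuple[float, float, float]]:
    """Non-overlapping disk placement with bounded retries."""
    w, h = config.roi_size_um
    placed: list[tuple[float, float, float]] = []
    for _ in range(config.plaques_per_roi):
        for attempt in range(config.max_placement_retries + 1):
            r = rng.uniform(*config.plaque_radius_um)
            cx = rng.uniform(r, w - r)
            cy = rng.uniform(r, h - r)
            if all(np.hypot(cx - px, cy - py) >= r + pr for px, py, pr in placed):
                placed.append((cx, cy, r))
                break
        else:
            raise RuntimeError(
                "plaque placement failed after "
                f"{config.max_placement_retries} retries (density too high)"
            )
    return placed


def simulate_imaging(config: ImagingSimConfig, seed: int | None = None):
    """Generate (ImagingCellTable, PlaqueSet, truth table).

    Truth has one row per cell with its true peri-plaque status (within
    ``peri_radius_um`` of a plaque boundary) and true marker states.
    Cells within the peri-plaque band get the boosted positivity rates.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    types = list(config.cell_type_weights)
    weights = np.array([config.cell_type_weights[t] for t in types])
    sen_channels = list(config.baseline_rates)
    ct_channels = sorted(set(CELL_TYPE_MARKER.values()))
    w, h = config.roi_size_um

    cell_rows = []
    truth_rows = []
    disk_rows = []
    cell_counter = 0
    for s in range(config.n_samples):
        sample_id = f"S{s + 1:02d}"
        for r_i in range(config.rois_per_sample):
            roi_id = f"{sample_id}_roi{r_i}"
            plaques = _place_plaques(rng, config)
            for p_i, (cx, cy, rad) in enumerate(plaques, start=1):
                disk_rows.append(
                    {"roi_id": roi_id, "plaque_id": p_i, "cx_um": cx, "cy_um": cy,
                     "radius_um": rad}
                )
            xs = rng.uniform(0, w, config.cells_per_roi)
            ys = rng.uniform(0, h, config.cells_per_roi)
            ct_draw = rng.choice(len(types), size=config.cells_per_roi, p=weights)
            for i in range(config.cells_per_roi):
                ct = types[ct_draw[i]]
                marker = CELL_TYPE_MARKER[ct]
                if plaques:
                    d = min(
                        max(np.hypot(xs[i] - cx, ys[i] - cy) - rad, 0.0)
                        for cx, cy, rad in plaques
                    )
                else:
                    d = np.inf
                peri = d <= config.peri_radius_um
                states = {}
                for ch in sen_channels:
                    rate = (
                        config.peri_boost.get(ch, config.baseline_rates[ch])
                        if peri
                        else config.baseline_rates[ch]
                    )
                    states[ch] = bool(rng.random() < rate)
                row = {
                    "cell_id": f"c{cell_counter:06d}",
                    "roi_id": roi_id,
                    "sample_id": sample_id,
                    "x_um": xs[i],
                    "y_um": ys[i],
                    "cluster_label": ct,
                }
                cell_counter += 1
                for ch in ct_channels:
                    positive = ch == marker
                    mu = config.intensity_pos_log_mean if positive else config.intensity_neg_log_mean
                    row[ch] = rng.lognormal(mu, config.intensity_log_sd)
                for ch in sen_channels:
                    mu = config.intensity_pos_log_mean if states[ch] else config.intensity_neg_log_mean
                    row[ch] = rng.lognormal(mu, config.intensity_log_sd)
                cell_rows.append(row)
                truth_rows.append(
                    {
                        "cell_id": row["cell_id"], "roi_id": roi_id, "sample_id": sample_id,
                        "cell_type": ct, "peri_plaque": peri, "distance_um": d,
                        **{f"{ch}_true": states[ch] for ch in sen_channels},
                    }
                )
    table = pd.DataFrame(cell_rows)
    cells = ImagingCellTable(table=table, channels=ct_channels + sen_channels)
    plaque_set = PlaqueSet(disks=pd.DataFrame(
        disk_rows, columns=["roi_id", "plaque_id", "cx_um", "cy_um", "radius_um"]
    ))
    truth = pd.DataFrame(truth_rows)
    return cells, plaque_set, truth
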