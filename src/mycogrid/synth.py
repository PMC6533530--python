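"""Synthetic box-screen experiments with a full truth ledger.

The generator reproduces the structure of the greenhouse screen: four
replicate runs, each a box divided into three treatment blocks (Control,
rock phosphate, rock phosphate + AM fungus), each block a 17 x 20 planting
grid holding one plant of each of 334 varieties (seven subgroups) plus six
check-cultivar cells, with the same within-run randomization shared by the
three treatments.

Shoot dry weight is generated on the log scale from a simultaneous
autoregressive (SAR) equilibrium per block,

    log SDW = (I - rho_t W)^-1 (mu + run + treatment + edge + exterior
                                + subgroup + variety + GxT + field + eps),

with row-normalized queen adjacency W and a treatment-ordered coupling
rho_t, so neighbor facilitation is strongest in the AM treatment.  Hyphal
colonization (AM blocks only) adds variety effects (polygenic plus a few
causal SNPs), focal- and neighbor-SDW slopes and a conditional
autoregressive (CAR) spatial field.  Genotypes are inbred dosages with
subgroup-divergent allele frequencies and block-wise linkage disequilibrium.

Default parameters are the study conditions: run means bracketing
78-125 mg, edge/exterior contrasts of a few percent on the log scale, mean
colonization near 55% spanning roughly 21-89%.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import geometry
from .gwas import GenotypeMatrix

__all__ = [
    "SimulationConfig", "SimulationTruth", "SimulatedExperiment",
    "simulate_genotypes", "simulate_sdw", "simulate_hc",
    "simulate_intersections", "simulate_experiment", "default_causal_snps",
]

# treatment block order along the box axis, south to north, per run
_RUN_TREATMENT_ORDER = {
    1: ("Control", "RP+AM", "RP"),
    2: ("RP+AM", "RP", "Control"),
    3: ("RP+AM", "RP", "Control"),
    4: ("RP", "Control", "RP+AM"),
}


@dataclass
class SimulationConfig:
    """All generator parameters; defaults are the screen's study conditions."""

    # design
    n_varieties: int = 334
    subgroup_sizes: dict = field(default_factory=lambda: {
        "ADMIX": 35, "AROMATIC": 12, "AUS": 54, "IND": 63,
        "TEJ": 82, "TRJ": 83, "OTHER": 5})
    n_checks: int = 6
    n_runs: int = 4
    treatments: tuple = ("Control", "RP", "RP+AM")
    rows: int = 17
    cols: int = 20
    spacing_cm: float = 5.0
    missing_rate: float = 0.02

    # genotypes
    n_snps: int = 5000
    n_chrom: int = 12
    snps_per_block: int = 10
    within_block_bp: int = 10_000
    block_gap_bp: int = 400_000
    fst: float = 0.15
    ld_copy_prob: float = 0.93
    het_rate: float = 0.02
    missing_call_rate: float = 0.01
    causal: Optional[list] = None   # list of (snp_index, beta); None -> defaults

    # shoot dry weight (log mg scale)
    sdw_mu_log: float = 4.569
    run_effects_log: tuple = (-0.212, -0.103, 0.056, 0.259)
    treatment_effects_log: tuple = (0.0, 0.01, -0.25)   # Control, RP, RP+AM
    edge_effect_log: float = 0.126
    exterior_effect_log: float = -0.076
    subgroup_sd_log: float = 0.10
    variety_sd_log: float = 0.30
    gxt_sd_log: float = 0.10
    spatial_sd_log: float = 0.12
    spatial_scope: str = "common"       # or "per_block"
    rho: tuple = (0.12, 0.30, 0.44)     # SAR coupling: Control, RP, RP+AM
    sdw_resid_sd_log: float = 0.25

    # hyphal colonization (percent scale, AM blocks only)
    hc_mean: float = 51.0
    hc_subgroup_sd: float = 2.0
    hc_polygenic_sd: float = 6.0
    hc_focal_slope: float = 15.0        # % per g focal SDW
    hc_neighbor_slope: float = 25.0     # % per g neighbor-mean SDW
    hc_interaction_slope: float = 0.0   # % per g^2, focal x neighbor product
    car_alpha: float = 0.9
    car_sd: float = 6.0
    hc_resid_sd: float = 10.0

    # intersection scoring
    n_intersections: int = 100
    arbuscule_frac: float = 0.3
    vesicle_frac: float = 0.2

    def __post_init__(self):
        if any(abs(r) >= 1 for r in self.rho):
            raise ValueError("SAR coupling |rho| must be < 1")
        if not 0 <= self.car_alpha < 1:
            raise ValueError("CAR alpha must be in [0, 1)")
        if sum(self.subgroup_sizes.values()) != self.n_varieties:
            raise ValueError("subgroup sizes must sum to n_varieties")
        if self.n_varieties + self.n_checks > self.rows * self.cols:
            raise ValueError("more plants than grid cells")
        if self.spatial_scope not in ("common", "per_block"):
            raise ValueError("spatial_scope must be 'common' or 'per_block'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["causal"] = [[int(i), float(b)] for i, b in (self.causal or [])] or None
        return d


def default_causal_snps(config: SimulationConfig) -> list:
    """Deterministic causal set: one mid-block SNP on alternate chromosomes.

    Four large effects (|beta| = 5.5 % per dosage unit, roughly 10-15% of
    cultivar-mean variance each) on chromosomes 1, 3, 5, 7 and four small
    (|beta| = 1.5) on 2, 4, 6, 8, alternating sign.
    """
    chroms, _ = _snp_map(config)
    chrom_list = [str(c) for c in range(1, config.n_chrom + 1)]
    large_chroms = chrom_list[0::2][:4]
    small_chroms = chrom_list[1::2][:4]
    out = []
    for i, c in enumerate(large_chroms):
        on_c = np.flatnonzero(chroms == c)
        j = min(config.snps_per_block + config.snps_per_block // 2, len(on_c) - 1)
        out.append((int(on_c[j]), 5.5 * (1 if i % 2 == 0 else -1)))
    for i, c in enumerate(small_chroms):
        on_c = np.flatnonzero(chroms == c)
        j = min(3 * config.snps_per_block + config.snps_per_block // 2, len(on_c) - 1)
        out.append((int(on_c[j]), 1.5 * (1 if i % 2 == 0 else -1)))
    return out


@dataclass
class SimulationTruth:
    """Everything the generator drew, sufficient to audit any recovery test."""

    config: dict
    variety_names: list
    subgroup_of: dict
    variety_sdw_effects: dict
    variety_hc_effects: dict
    subgroup_sdw_effects: dict
    subgroup_hc_effects: dict
    gxt_effects: dict
    causal: list                    # [(snp_id, beta)]
    causal_indices: list
    rho_by_treatment: dict
    spatial_field_sd: float
    car_field_sd: float
    hc_variety_var: float           # realized variance of variety HC effects
    hc_resid_var: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulatedExperiment:
    plants: pd.DataFrame
    genotypes: GenotypeMatrix
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _snp_map(config: SimulationConfig):
    """(chrom, pos) for every SNP: LD blocks separated by recombination gaps."""
    per_chrom = config.n_snps // config.n_chrom
    extra = config.n_snps - per_chrom * config.n_chrom
    chroms, poss = [], []
    for c in range(1, config.n_chrom + 1):
        n_c = per_chrom + (1 if c <= extra else 0)
        pos = 1
        for j in range(n_c):
            if j and j % config.snps_per_block == 0:
                pos += config.block_gap_bp
            elif j:
                pos += config.within_block_bp
            chroms.append(str(c))
            poss.append(pos)
    return np.array(chroms), np.array(poss, dtype=np.int64)


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator):
    """Inbred dosage matrix with subgroup divergence and block-wise LD.

    Subgroup allele frequencies follow a Balding--Nichols model around a
    shared ancestral frequency (divergence ``fst``); within an LD block each
    accession's allele copies the previous SNP's allele with probability
    ``ld_copy_prob``, giving dosage correlation of that order between
    adjacent SNPs.  Dosages are mostly homozygous (0/2) with a small
    heterozygosity and missing-call rate.

    Returns ``(GenotypeMatrix, subgroup_of)`` over variety accessions
    (checks carry no genotype).
    """
    chroms, poss = _snp_map(config)
    m = config.n_snps
    varieties = [f"V{i + 1:03d}" for i in range(config.n_varieties)]
    subgroup_of, start = {}, 0
    for sg, size in config.subgroup_sizes.items():
        for v in varieties[start:start + size]:
            subgroup_of[v] = sg
        start += size

    p_anc = rng.uniform(0.1, 0.9, size=m)
    fst = max(config.fst, 1e-6)
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    sg_names = list(config.subgroup_sizes)
    p_sg = {sg: np.clip(rng.beta(a, b), 0.01, 0.99) for sg in sg_names}

    alleles = np.empty((config.n_varieties, m))
    row = 0
    for sg in sg_names:
        size = config.subgroup_sizes[sg]
        p = p_sg[sg]
        block_start = np.zeros(m, bool)
        per_chrom_counter = 0
        last_chrom = None
        for j in range(m):
            if chroms[j] != last_chrom:
                per_chrom_counter = 0
                last_chrom = chroms[j]
            block_start[j] = per_chrom_counter % config.snps_per_block == 0
            per_chrom_counter += 1
        h = np.empty((size, m))
        for j in range(m):
            fresh = rng.random(size) < p[j]
            if block_start[j]:
                h[:, j] = fresh
            else:
                copy = rng.random(size) < config.ld_copy_prob
                h[:, j] = np.where(copy, h[:, j - 1], fresh)
        alleles[row:row + size] = h
        row += size

    dos = 2.0 * alleles
    het = rng.random(dos.shape) < config.het_rate
    dos[het] = 1.0
    miss = rng.random(dos.shape) < config.missing_call_rate
    dos[miss] = np.nan

    gm = GenotypeMatrix(
        snp_ids=np.array([f"snp{c}_{p}" for c, p in zip(chroms, poss)]),
        chrom=chroms, pos=poss, dosages=dos, samples=varieties)
    return gm, subgroup_of


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def _make_layout(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Plant placement for all runs; same randomization across a run's blocks."""
    varieties = [f"V{i + 1:03d}" for i in range(config.n_varieties)]
    checks = [f"CHECK{i + 1}" for i in range(config.n_checks)]
    cells = [(r, c) for r in range(1, config.rows + 1) for c in range(1, config.cols + 1)]
    n_cells = len(cells)
    rows = []
    for run in range(1, config.n_runs + 1):
        order = _RUN_TREATMENT_ORDER.get(run) or tuple(
            rng.permutation(list(config.treatments)))
        box = 1 if run in (1, 3) else 2
        names = varieties + checks
        names = names + [None] * (n_cells - len(names))
        placement = list(rng.permutation(np.arange(n_cells)))
        for order_in_box, treatment in enumerate(order, start=1):
            layout = geometry.GridLayout(
                rows=config.rows, cols=config.cols, spacing_cm=config.spacing_cm,
                block_id=f"r{run}.{treatment}", block_order_in_box=order_in_box)
            for cell_i, name_i in enumerate(placement):
                r, c = cells[cell_i]
                name = names[name_i]
                if name is None:
                    continue
                e, x = geometry.edge_flags(layout, (r, c))
                rows.append({
                    "run": run, "box": box, "block": layout.block_id,
                    "block_order": order_in_box, "treatment": treatment,
                    "row": r, "col": c, "cell": f"r{r}c{c}",
                    "variety": name, "is_check": name.startswith("CHECK"),
                    "edge": e, "exterior": x,
                })
    return pd.DataFrame(rows)


def _queen_W(config: SimulationConfig):
    """Row-normalized queen adjacency over the block lattice, plus cell order."""
    layout = geometry.GridLayout(rows=config.rows, cols=config.cols)
    cells = list(layout.positions())
    ix = {p: i for i, p in enumerate(cells)}
    W = np.zeros((len(cells), len(cells)))
    for p in cells:
        nbrs = geometry.first_order_neighbors(layout, p)
        for q in nbrs:
            W[ix[p], ix[q]] = 1.0 / len(nbrs)
    A = (W > 0).astype(float)
    return W, A, cells


def _smooth_field(gx, gy, sd, rng):
    """Low-frequency sinusoidal surface scaled to the requested SD."""
    f = np.zeros(len(gx), float)
    for _ in range(3):
        ux, uy = rng.uniform(0.2, 0.8, 2)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        f += amp * np.sin(2 * np.pi * (ux * gx / max(gx.max(), 1)
                                       + uy * gy / max(gy.max(), 1)) + phase)
    s = f.std()
    return f * (sd / s) if s > 0 else f


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_sdw(plants: pd.DataFrame, variety_effects: dict, gxt_effects: dict,
                 subgroup_effects: dict, config: SimulationConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Add ``sdw_mg`` via the per-block SAR equilibrium on the log scale."""
    W, _, cells = _queen_W(config)
    cell_ix = {f"r{r}c{c}": i for i, (r, c) in enumerate(cells)}
    rho_of = dict(zip(config.treatments, config.rho))
    treat_eff = dict(zip(config.treatments, config.treatment_effects_log))
    for t, rho in rho_of.items():
        if abs(rho) * np.abs(np.linalg.eigvals(W)).max() >= 1:
            raise ValueError(f"SAR unstable for treatment {t!r} (rho={rho})")

    plants = plants.copy()
    plants["sdw_mg"] = np.nan
    # shared spatial field over global (box-axis, width) coordinates
    gx = (plants["block_order"] - 1) * config.rows + plants["row"]
    gy = plants["col"].to_numpy(float)
    if config.spatial_scope == "common":
        field_all = _smooth_field(gx.to_numpy(float), gy, config.spatial_sd_log, rng)
        plants["_field"] = field_all
    else:
        plants["_field"] = 0.0
        for b, sub in plants.groupby("block"):
            f = _smooth_field(sub["row"].to_numpy(float), sub["col"].to_numpy(float),
                              config.spatial_sd_log, rng)
            plants.loc[sub.index, "_field"] = f

    for (run, block), sub in plants.groupby(["run", "block"], sort=True):
        t = sub["treatment"].iloc[0]
        eta_cells = np.zeros(len(cells))
        present = np.zeros(len(cells), bool)
        idx = [cell_ix[c] for c in sub["cell"]]
        eps = rng.normal(0, config.sdw_resid_sd_log, size=len(sub))
        eta = (config.sdw_mu_log
               + config.run_effects_log[(run - 1) % len(config.run_effects_log)]
               + treat_eff[t]
               + config.edge_effect_log * sub["edge"].to_numpy()
               + config.exterior_effect_log * sub["exterior"].to_numpy()
               + np.array([subgroup_effects[s] for s in sub["subgroup"]])
               + np.array([variety_effects[v] for v in sub["variety"]])
               + np.array([gxt_effects[(v, t)] for v in sub["variety"]])
               + sub["_field"].to_numpy()
               + eps)
        eta_cells[idx] = eta
        present[idx] = True
        # empty cells (if any) carry the block mean so they do not distort SAR
        eta_cells[~present] = eta.mean()
        s_log = np.linalg.solve(np.eye(len(cells)) - rho_of[t] * W, eta_cells)
        # the SAR equilibrium scales a constant mean by 1/(1-rho); recenter the
        # block so marginal means stay at the configured anchors while the
        # neighbor-interaction structure of the deviations is preserved
        s_log += eta_cells.mean() - s_log.mean()
        plants.loc[sub.index, "sdw_mg"] = np.exp(s_log[idx])

    plants.drop(columns="_field", inplace=True)
    # dead/missing plants
    dead = rng.random(len(plants)) < config.missing_rate
    plants.loc[dead, "sdw_mg"] = np.nan
    return plants


def _car_field(A, alpha, sd, rng):
    """Sample a zero-mean CAR field with precision (D - alpha A), scaled to sd."""
    D = np.diag(A.sum(axis=1))
    Q = D - alpha * A
    L = np.linalg.cholesky(Q)
    z = rng.normal(size=A.shape[0])
    x = np.linalg.solve(L.T, z)
    x -= x.mean()
    s = x.std()
    return x * (sd / s) if s > 0 else x


def simulate_hc(plants: pd.DataFrame, variety_hc: dict, subgroup_hc: dict,
                config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Add colonization percentages for plants in the AM treatment.

    HC = mean + subgroup + variety + b1 * SDW(g) + b2 * neighbor-mean SDW(g)
    + CAR field + noise, truncated to [0, 100]; arbuscule / vesicle
    percentages are drawn per plant through intersection scoring.
    """
    W, A, cells = _queen_W(config)
    cell_ix = {f"r{r}c{c}": i for i, (r, c) in enumerate(cells)}
    layout = geometry.GridLayout(rows=config.rows, cols=config.cols)

    plants = plants.copy()
    for col in ("hyphae_pct", "arbuscule_pct", "vesicle_pct", "hyphae_only_pct"):
        plants[col] = np.nan

    am = plants[(plants["treatment"] == "RP+AM") & plants["sdw_mg"].notna()]
    for block, sub in am.groupby("block", sort=True):
        value_map = {(r, c): s / 1000.0
                     for r, c, s in zip(sub["row"], sub["col"], sub["sdw_mg"])}
        nbar = np.array([geometry.neighbor_mean(layout, value_map, (r, c))
                         for r, c in zip(sub["row"], sub["col"])])
        nbar = np.where(np.isfinite(nbar), nbar, np.nanmean(nbar))
        car = _car_field(A, config.car_alpha, config.car_sd, rng)
        idx = [cell_ix[c] for c in sub["cell"]]
        hc = (config.hc_mean
              + np.array([subgroup_hc[s] for s in sub["subgroup"]])
              + np.array([variety_hc[v] for v in sub["variety"]])
              + config.hc_focal_slope * sub["sdw_mg"].to_numpy() / 1000.0
              + config.hc_neighbor_slope * nbar
              + config.hc_interaction_slope * sub["sdw_mg"].to_numpy() / 1000.0 * nbar
              + car[idx]
              + rng.normal(0, config.hc_resid_sd, len(sub)))
        hc = np.clip(hc, 0.0, 100.0)
        # push the latent rate through intersection counting
        for i, (pi, rate) in enumerate(zip(sub.index, hc)):
            rec = simulate_intersections(rate, config, rng)
            counts = {c: rec.count(c) for c in set(rec)}
            n = len(rec)
            h = 100.0 * counts.get("hyphae_only", 0) / n
            a_ = 100.0 * counts.get("arbuscule", 0) / n
            v_ = 100.0 * counts.get("vesicle", 0) / n
            plants.loc[pi, ["hyphae_only_pct", "arbuscule_pct", "vesicle_pct",
                            "hyphae_pct"]] = (h, a_, v_, h + a_ + v_)
    return plants


def simulate_intersections(true_rate: float, config: SimulationConfig,
                           rng: np.random.Generator) -> list:
    """Per-intersection categories for one plant at a latent hyphal rate (%)."""
    if not 0 <= true_rate <= 100:
        raise ValueError("rate must be in [0, 100]")
    n = config.n_intersections
    pos = rng.random(n) < true_rate / 100.0
    cats = []
    for hit in pos:
        if not hit:
            cats.append("none")
            continue
        u = rng.random()
        if u < config.arbuscule_frac:
            cats.append("arbuscule")
        elif u < config.arbuscule_frac + config.vesicle_frac:
            cats.append("vesicle")
        else:
            cats.append("hyphae_only")
    return cats


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_experiment(config: Optional[SimulationConfig] = None,
                        seed: int = 0) -> SimulatedExperiment:
    """Generate a complete experiment (genotypes, layout, SDW, HC) plus truth."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)

    genotypes, subgroup_of = simulate_genotypes(config, rng)
    causal = config.causal if config.causal is not None else default_causal_snps(config)

    varieties = genotypes.samples
    checks = [f"CHECK{i + 1}" for i in range(config.n_checks)]
    sg_names = list(config.subgroup_sizes)
    subgroup_sdw = {sg: rng.normal(0, config.subgroup_sd_log) for sg in sg_names}
    subgroup_hc = {sg: rng.normal(0, config.hc_subgroup_sd) for sg in sg_names}
    variety_sdw = {v: rng.normal(0, config.variety_sd_log) for v in varieties}
    gxt = {(v, t): rng.normal(0, config.gxt_sd_log)
           for v in varieties for t in config.treatments}

    # variety HC effects: causal SNP contributions plus a polygenic residual
    mu_d = np.nanmean(genotypes.dosages, axis=0)
    variety_hc = {}
    for i, v in enumerate(varieties):
        g = 0.0
        for idx, beta in causal:
            dv = genotypes.dosages[i, idx]
            if np.isnan(dv):
                dv = mu_d[idx]
            g += beta * (dv - mu_d[idx])
        variety_hc[v] = g + rng.normal(0, config.hc_polygenic_sd)
    for c in checks:
        subgroup_of[c] = "CHECK"
        variety_sdw[c] = rng.normal(0, config.variety_sd_log)
        variety_hc[c] = rng.normal(0, config.hc_polygenic_sd)
        for t in config.treatments:
            gxt[(c, t)] = rng.normal(0, config.gxt_sd_log)
    subgroup_sdw["CHECK"] = 0.0
    subgroup_hc["CHECK"] = 0.0

    plants = _make_layout(config, rng)
    plants["subgroup"] = [subgroup_of[v] for v in plants["variety"]]
    plants = simulate_sdw(plants, variety_sdw, gxt, subgroup_sdw, config, rng)
    plants = simulate_hc(plants, variety_hc, subgroup_hc, config, rng)

    hc_vals = np.array([variety_hc[v] for v in varieties])
    truth = SimulationTruth(
        config=config.to_dict(),
        variety_names=list(varieties),
        subgroup_of=dict(subgroup_of),
        variety_sdw_effects={v: float(variety_sdw[v]) for v in variety_sdw},
        variety_hc_effects={v: float(variety_hc[v]) for v in variety_hc},
        subgroup_sdw_effects={k: float(v) for k, v in subgroup_sdw.items()},
        subgroup_hc_effects={k: float(v) for k, v in subgroup_hc.items()},
        gxt_effects={f"{v}|{t}": float(e) for (v, t), e in gxt.items()},
        causal=[[str(genotypes.snp_ids[i]), float(b)] for i, b in causal],
        causal_indices=[[int(i), float(b)] for i, b in causal],
        rho_by_treatment=dict(zip(config.treatments, map(float, config.rho))),
        spatial_field_sd=float(config.spatial_sd_log),
        car_field_sd=float(config.car_sd),
        hc_variety_var=float(hc_vals.var()),
        hc_resid_var=float(config.hc_resid_sd ** 2),
    )
    return SimulatedExperiment(plants=plants, genotypes=genotypes, truth=truth)
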