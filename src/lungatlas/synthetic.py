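"""Synthetic count-matrix generator emulating the perinatal lung immune atlas.

The generator draws negative-binomial (gamma-Poisson) counts from
population-specific expression profiles at Smart-seq2-scale library
sizes.  Its default design mirrors the study layout the pipeline is
built for: eight mice (one female, one male at each of E18.5, P1, P7
and P21), ~15 immune populations of which five are macrophage/monocyte
states sharing a Cd68-like marker, a developmental-gradient population
whose latent time drives a monotone expression program, contaminating
non-immune doublets, and a fraction of low-depth failed cells.

Every cell's truth (population, latent time, doublet/low-depth status,
proliferation status) is returned alongside the counts so downstream
stages can be validated against planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import TIMEPOINTS, CountMatrix

# population layout: five macrophage/monocyte states, three DC states,
# four lymphocyte and three granulocyte populations = 15
POPULATION_NAMES = (
    "Mac I", "Mac II", "Mac III", "Mac IV", "Mac V",
    "cDC1", "cDC2", "Mig-DC",
    "B", "T", "NK", "ILC2",
    "mast", "basophil", "neutrophil",
)
MACROPHAGE_POPULATIONS = POPULATION_NAMES[:5]

#: canonical first marker per population (mouse gene symbols)
CANONICAL_MARKERS = {
    "Mac I": "Gal", "Mac II": "Itgax", "Mac III": "Car4", "Mac IV": "C1qa",
    "Mac V": "Plac8", "cDC1": "Itgae", "cDC2": "Cd209a", "Mig-DC": "Mreg",
    "B": "Ms4a1", "T": "Cd3e", "NK": "Gzma", "ILC2": "Areg",
    "mast": "Mcpt4", "basophil": "Mcpt8", "neutrophil": "Retnlg",
}

SHARED_MACROPHAGE_MARKER = "Cd68"
IMMUNE_MARKER = "Ptprc"  # Cd45; expressed by every immune cell
CONTAMINANT_MARKERS = (
    "Epcam", "Krt8", "Krt18", "Sftpc",          # epithelial
    "Cdh5", "Pecam1", "Cldn5",                  # endothelial
    "Col6a2", "Col1a1", "Col3a1", "Dcn", "Acta2",  # mesenchymal
)
PROLIFERATION_MARKERS = ("Mki67", "Mcm5")

# relative population frequencies per timepoint (normalized on use);
# follows the study narrative: Mac I dominates the m/m compartment
# before birth and is nearly absent by P7; lymphocytes rise to the
# majority by P21 (B ~30%, T ~15%).  Rare populations are floored so
# each remains clusterable at the simulated scale.
DEFAULT_COMPOSITION = pd.DataFrame(
    [
        [0.48, 0.05, 0.02, 0.03, 0.02, 0.03, 0.04, 0.02, 0.03, 0.03, 0.03, 0.04, 0.06, 0.04, 0.08],
        [0.20, 0.12, 0.06, 0.05, 0.04, 0.03, 0.05, 0.02, 0.08, 0.06, 0.04, 0.04, 0.05, 0.04, 0.12],
        [0.01, 0.10, 0.09, 0.06, 0.04, 0.03, 0.05, 0.03, 0.16, 0.10, 0.05, 0.05, 0.06, 0.04, 0.13],
        [0.01, 0.06, 0.07, 0.05, 0.03, 0.03, 0.04, 0.03, 0.30, 0.15, 0.05, 0.04, 0.04, 0.03, 0.07],
    ],
    index=list(TIMEPOINTS),
    columns=list(POPULATION_NAMES),
)

# fraction of proliferating (Mki67/Mcm5+) macrophage/monocyte cells per
# timepoint: proliferation is highest before birth and declines
DEFAULT_PROLIFERATION = {"E18.5": 0.6, "P1": 0.4, "P7": 0.2, "P21": 0.1}


class DesignError(ValueError):
    """Raised when an AtlasDesign is internally infeasible."""


@dataclass
class AtlasDesign:
    """Parameters of the synthetic atlas.

    Defaults reproduce the study conditions at desk scale: 8 mice
    (2 per timepoint) x 250 cells = 2000 cells, 2000 genes, 15
    populations with 20 markers each elevated ``marker_fold``-fold,
    log-normal Smart-seq2 library sizes (median 3e5 read pairs).
    """

    n_populations: int = 15
    markers_per_population: int = 20
    n_genes: int = 2000
    cells_per_mouse: int = 250
    mice_per_timepoint: int = 2
    timepoints: tuple = TIMEPOINTS
    composition: pd.DataFrame | None = None  # timepoint x population weights
    gradient_population: str | None = "Mac II"
    n_gradient_genes: int = 30
    gradient_amplitude_cpm: float = 1000.0
    mouse_effect_sd: float = 0.0
    doublet_fraction: float = 0.03
    lowdepth_fraction: float = 0.05
    base_dispersion: float = 0.15
    marker_fold: float = 500.0
    marker_baseline_cpm: float = 0.5
    contaminant_cpm: float = 2_000.0
    immune_marker_cpm: float = 60.0
    median_library: float = 300_000.0
    library_sigma: float = 0.35
    lowdepth_range: tuple = (5_000.0, 40_000.0)
    proliferation_by_timepoint: dict = field(
        default_factory=lambda: dict(DEFAULT_PROLIFERATION)
    )
    prolif_marker_cpm: float = 100.0
    seed: int = 0

    @property
    def population_names(self) -> list[str]:
        if self.n_populations <= len(POPULATION_NAMES):
            return list(POPULATION_NAMES[: self.n_populations])
        extra = [f"pop{i}" for i in range(len(POPULATION_NAMES), self.n_populations)]
        return list(POPULATION_NAMES) + extra

    @property
    def macrophage_population_names(self) -> list[str]:
        return [p for p in self.population_names if p in MACROPHAGE_POPULATIONS]

    def resolved_composition(self) -> pd.DataFrame:
        comp = self.composition
        if comp is None:
            comp = DEFAULT_COMPOSITION.loc[list(self.timepoints), self.population_names]
        comp = comp.astype(float)
        comp = comp.div(comp.sum(axis=1), axis=0)  # rows on the simplex
        return comp

    def validate(self) -> None:
        n_special = (
            self.n_populations * self.markers_per_population
            + 1  # shared macrophage marker
            + 1  # immune marker
            + len(CONTAMINANT_MARKERS)
            + len(PROLIFERATION_MARKERS)
            + self.n_gradient_genes
        )
        if n_special > self.n_genes:
            raise DesignError(
                f"design needs {n_special} dedicated genes but n_genes={self.n_genes}"
            )
        if not 0 <= self.doublet_fraction < 1:
            raise DesignError("doublet_fraction must be in [0, 1)")
        if not 0 <= self.lowdepth_fraction < 1:
            raise DesignError("lowdepth_fraction must be in [0, 1)")
        if self.base_dispersion <= 0:
            raise DesignError("base_dispersion must be > 0")
        comp = self.resolved_composition()
        if comp.isna().any().any():
            raise DesignError("composition contains NaN after normalization")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated atlas."""

    cell_data: pd.DataFrame  # population, latent_time, is_doublet, is_lowdepth, is_proliferating
    marker_of: dict  # gene symbol -> population it marks
    gradient_genes: list
    contaminant_genes: list
    mouse_effects: dict  # mouse_id -> per-gene multiplicative effect
    design: AtlasDesign


def _build_gene_table(design: AtlasDesign, rng: np.random.Generator):
    """Lay out gene symbols and per-population mean CPM profiles.

    Returns (symbols, profiles, marker_of, gradient_cols, contaminant_cols,
    early_cols, late_cols).  ``profiles`` is population x gene mean CPM,
    un-normalized; rows are normalized to 1e6 at draw time.
    """
    pops = design.population_names
    n_pops = len(pops)
    mk = design.markers_per_population

    symbols: list[str] = []
    marker_of: dict[str, str] = {}
    for p in pops:
        first = CANONICAL_MARKERS.get(p, f"{p}_mk0")
        names = [first] + [f"{first}l{j}" for j in range(1, mk)]  # marker-like analogues
        for s in names:
            marker_of[s] = p
        symbols.extend(names)
    symbols.append(SHARED_MACROPHAGE_MARKER)
    symbols.append(IMMUNE_MARKER)
    symbols.extend(CONTAMINANT_MARKERS)
    symbols.extend(PROLIFERATION_MARKERS)
    grad_names = [f"Grad{j:02d}" for j in range(design.n_gradient_genes)]
    symbols.extend(grad_names)
    n_background = design.n_genes - len(symbols)
    symbols.extend(f"Gene{j:04d}" for j in range(n_background))

    col = {s: i for i, s in enumerate(symbols)}
    profiles = np.zeros((n_pops, design.n_genes))

    # background genes: shared log-normal relative means across
    # populations, rescaled below so every profile row sums to 1e6 CPM
    bg_cols = np.array([col[f"Gene{j:04d}"] for j in range(n_background)])
    bg_means = rng.lognormal(mean=0.0, sigma=1.0, size=n_background)
    profiles[:, bg_cols] = bg_means[None, :]

    # markers: low baseline everywhere, elevated marker_fold-fold at home
    base = design.marker_baseline_cpm
    marker_cols = np.array([col[s] for s in marker_of])
    marker_home = np.array([pops.index(marker_of[s]) for s in marker_of])
    profiles[:, marker_cols] = base
    profiles[marker_home, marker_cols] = base * design.marker_fold

    # Itgax (Mac II's canonical marker) is also elevated in Mac III,
    # matching the annotation panel's Car4+Itgax rule for Mac III
    if "Itgax" in col and "Mac III" in pops and "Mac II" in pops:
        profiles[pops.index("Mac III"), col["Itgax"]] = base * design.marker_fold

    # shared macrophage marker high in all five m/m populations
    profiles[:, col[SHARED_MACROPHAGE_MARKER]] = base
    for p in design.macrophage_population_names:
        profiles[pops.index(p), col[SHARED_MACROPHAGE_MARKER]] = base * design.marker_fold

    # immune marker (Cd45-like) expressed by every immune population
    profiles[:, col[IMMUNE_MARKER]] = design.immune_marker_cpm

    # contaminants: essentially absent from immune cells
    contaminant_cols = np.array([col[s] for s in CONTAMINANT_MARKERS])
    profiles[:, contaminant_cols] = 0.02

    # proliferation markers: zero baseline (planted per cell later)
    prolif_cols = np.array([col[s] for s in PROLIFERATION_MARKERS])
    profiles[:, prolif_cols] = 0.02

    # gradient program: split into an early half (declines with latent
    # time) and a late half (rises); zero in non-gradient populations
    grad_cols = np.array([col[s] for s in grad_names]) if grad_names else np.array([], int)
    profiles[:, grad_cols] = 0.02
    half = design.n_gradient_genes // 2
    early_cols = grad_cols[:half]
    late_cols = grad_cols[half:]

    # anchor rows on the CPM scale: background genes absorb whatever the
    # dedicated genes leave of the 1e6 total
    special = np.ones(design.n_genes, bool)
    special[bg_cols] = False
    special_total = profiles[:, special].sum(axis=1)
    bg_target = 1e6 - special_total
    if np.any(bg_target <= 0):
        raise DesignError("dedicated genes exceed the 1e6 CPM budget")
    bg_current = profiles[:, bg_cols].sum(axis=1)
    profiles[:, bg_cols] *= (bg_target / bg_current)[:, None]
    return symbols, profiles, marker_of, grad_cols, contaminant_cols, early_cols, late_cols


def generate_atlas(design: AtlasDesign | None = None, seed: int | None = None):
    """Generate a synthetic atlas.

    Returns ``(CountMatrix, SyntheticTruth)``.  Identical design and
    seed give bit-identical output.
    """
    design = design or AtlasDesign()
    if seed is not None:
        design = _replace_seed(design, seed)
    design.validate()
    rng = np.random.default_rng(design.seed)
    pops = design.population_names
    comp = design.resolved_composition()

    (symbols, profiles, marker_of, grad_cols, contaminant_cols,
     early_cols, late_cols) = _build_gene_table(design, rng)
    n_genes = design.n_genes
    grad_pop_idx = (
        pops.index(design.gradient_population)
        if design.gradient_population in pops
        else None
    )

    # --- cell layout -------------------------------------------------
    rows = []
    for tp in design.timepoints:
        for mi in range(design.mice_per_timepoint):
            mouse_id = f"{tp}_m{mi + 1}"
            sex = "female" if mi % 2 == 0 else "male"
            pop_idx = rng.choice(
                len(pops), size=design.cells_per_mouse, p=comp.loc[tp].to_numpy()
            )
            for ci, pi in enumerate(pop_idx):
                rows.append((f"{mouse_id}_c{ci:04d}", mouse_id, sex, tp, pi))
    cells = pd.DataFrame(rows, columns=["cell_id", "mouse_id", "sex", "timepoint", "pop_idx"])
    n_cells = len(cells)

    u = rng.random(n_cells)
    is_doublet = u < design.doublet_fraction
    is_lowdepth = (~is_doublet) & (
        u < design.doublet_fraction + design.lowdepth_fraction
    )

    # latent time for gradient-population singlets
    latent = np.full(n_cells, np.nan)
    if grad_pop_idx is not None:
        in_grad = (cells["pop_idx"].to_numpy() == grad_pop_idx) & ~is_doublet
        latent[in_grad] = rng.random(int(in_grad.sum()))

    # proliferation status among macrophage/monocyte singlets
    mac_idx = {pops.index(p) for p in design.macrophage_population_names}
    is_prolif = np.zeros(n_cells, bool)
    pop_arr = cells["pop_idx"].to_numpy()
    for tp in design.timepoints:
        frac = design.proliferation_by_timepoint.get(tp, 0.0)
        sel = (
            (cells["timepoint"] == tp).to_numpy()
            & np.isin(pop_arr, list(mac_idx))
            & ~is_doublet
        )
        is_prolif[sel] = rng.random(int(sel.sum())) < frac

    # per-mouse multiplicative gene effects (log-normal)
    mouse_ids = cells["mouse_id"].unique()
    mouse_effects = {}
    for m in mouse_ids:
        if design.mouse_effect_sd > 0:
            mouse_effects[m] = rng.lognormal(0.0, design.mouse_effect_sd, size=n_genes)
        else:
            mouse_effects[m] = np.ones(n_genes)

    # --- mean CPM per cell -------------------------------------------
    mean_cpm = profiles[pop_arr].copy()

    if grad_pop_idx is not None:
        gmask = ~np.isnan(latent)
        t = latent[gmask][:, None]
        amp = design.gradient_amplitude_cpm
        mean_cpm[np.ix_(gmask, early_cols)] = amp * (1.0 - t)
        mean_cpm[np.ix_(gmask, late_cols)] = amp * t

    if is_prolif.any():
        prolif_cols = [symbols.index(s) for s in PROLIFERATION_MARKERS]
        mean_cpm[np.ix_(is_prolif, prolif_cols)] = design.prolif_marker_cpm

    # doublets: average of two populations' profiles + contaminant block
    if is_doublet.any():
        d_idx = np.flatnonzero(is_doublet)
        partner = rng.integers(0, len(pops), size=d_idx.size)
        # ensure the partner population differs from the cell's own
        same = partner == pop_arr[d_idx]
        partner[same] = (partner[same] + 1) % len(pops)
        mean_cpm[d_idx] = 0.5 * (profiles[pop_arr[d_idx]] + profiles[partner])
        mean_cpm[np.ix_(d_idx, contaminant_cols)] = design.contaminant_cpm

    # per-mouse effects then row renormalization to probabilities
    for m in mouse_ids:
        if design.mouse_effect_sd > 0:
            sel = (cells["mouse_id"] == m).to_numpy()
            mean_cpm[sel] *= mouse_effects[m][None, :]
    probs = mean_cpm / mean_cpm.sum(axis=1, keepdims=True)

    # --- library sizes and gamma-Poisson draw ------------------------
    lib = rng.lognormal(np.log(design.median_library), design.library_sigma, size=n_cells)
    lo, hi = design.lowdepth_range
    lib[is_lowdepth] = rng.uniform(lo, hi, size=int(is_lowdepth.sum()))

    mu = probs * lib[:, None]
    shape = 1.0 / design.base_dispersion
    lam = rng.gamma(shape, mu * design.base_dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    mapped_reads = counts.sum(axis=1)
    cell_annot = pd.DataFrame(
        {
            "cell_id": cells["cell_id"],
            "mouse_id": cells["mouse_id"],
            "sex": cells["sex"],
            "timepoint": cells["timepoint"],
            "mapped_reads": mapped_reads,
            "n_genes": (counts > 0).sum(axis=1),
        }
    )
    matrix = CountMatrix(counts=sp.csr_matrix(counts), cells=cell_annot, genes=symbols)

    population = np.array([pops[i] for i in pop_arr], dtype=object)
    population[is_doublet] = "doublet"
    truth = SyntheticTruth(
        cell_data=pd.DataFrame(
            {
                "cell_id": cells["cell_id"],
                "population": population,
                "latent_time": latent,
                "is_doublet": is_doublet,
                "is_lowdepth": is_lowdepth,
                "is_proliferating": is_prolif,
            }
        ),
        marker_of=marker_of,
        gradient_genes=[symbols[j] for j in grad_cols],
        contaminant_genes=list(CONTAMINANT_MARKERS),
        mouse_effects=mouse_effects,
        design=design,
    )
    return matrix, truth


def _replace_seed(design: AtlasDesign, seed: int) -> AtlasDesign:
    import dataclasses

    return dataclasses.replace(design, seed=seed)


def generate_germline_table(
    n_cells: int,
    shm_rate: float,
    seed: int = 0,
    v_length: int = 300,
    j_length: int = 40,
) -> pd.DataFrame:
    """Simulate per-cell BCR V/J germline-identity fractions.

    Each cell carries a heavy and a light chain; somatic hypermutation
    is a per-site Bernoulli(shm_rate) process over the effective V and
    J segment lengths, so identity = 1 - mutated_sites / length.  With
    ``shm_rate=0`` every identity is exactly 1.0.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    recs = []
    for chain in ("heavy", "light"):
        v_mut = rng.binomial(v_length, shm_rate, size=n_cells)
        j_mut = rng.binomial(j_length, shm_rate, size=n_cells)
        for i in range(n_cells):
            recs.append(
                (
                    f"cell{i:04d}",
                    chain,
                    1.0 - v_mut[i] / v_length,
                    1.0 - j_mut[i] / j_length,
                )
            )
    return pd.DataFrame(recs, columns=["cell_id", "chain", "v_identity", "j_identity"])
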