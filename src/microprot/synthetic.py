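"""Synthetic study generator: proteomes, batch growth curves, PSM tables,
and cytometry event tables with known ground truth.

Every input the analysis pipeline consumes can be generated here with
known parameters, so each downstream estimator can be checked against
the value that generated the data.  The generator encodes the study
conditions it emulates:

* a growth-law allocation in which the ribosomal proteome fraction rises
  linearly with growth rate, phi_ribo(mu) = phi0 + k*mu;
* component-specific amino-acid biases (ribosomal proteins enriched in
  Arg/Lys/Met/Val, cytoplasmic/membrane proteins in Cys/Leu/Phe/Thr/
  Trp/Tyr);
* dual-Monod batch growth with carbon, nitrogen, or concurrent
  limitation, with composition observables following simple linear
  rules in mu (nucleic-acid signal rising, protein fraction falling);
* stained-event fluorescence mixtures with optional doublets.

All randomness flows through numpy Generators derived from the single
config seed, so identical seed + config gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .constants import AA_ORDER
from .cytometry import EventTable, write_events
from .ontology import GoGraph
from .proteome import ProteinDB, ProteinRecord, write_fasta
from .quant import PsmRow, PsmTable, write_psm_csv

Limitation = Literal["carbon", "nitrogen", "dual"]
Panel = Literal["SG", "SGPI", "BODIPY_SYTO62"]

#: Simplified component label each synthetic component maps to after the
#: GO collapse (the "unannotated" component receives no label).
COMPONENT_TO_LABEL = {
    "ribosome": "ribosome",
    "cytoplasm": "cytoplasm",
    "membrane": "membrane",
    "protein_complex": "protein containing complexes",
}

_LIMITATION_TAG = {"carbon": 0, "nitrogen": 1, "dual": 2}
_PANEL_TAG = {"SG": 0, "SGPI": 1, "BODIPY_SYTO62": 2}


class ConfigError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


# ---------------------------------------------------------------------------
# Configuration


def _default_aa_bias() -> dict[str, np.ndarray]:
    """Per-component amino-acid sampling weights.

    A flat background with ribosomal proteins enriched 1.6x in
    Arg/Lys/Met/Val and cytoplasmic/membrane proteins enriched 1.3x in
    Cys/Leu/Phe/Thr/Trp/Tyr, reproducing the direction of the known
    compositional contrast between ribosomal and metabolic proteins.
    """
    base = np.ones(len(AA_ORDER))
    idx = {aa: i for i, aa in enumerate(AA_ORDER)}
    ribo = base.copy()
    for aa in "RKMV":
        ribo[idx[aa]] *= 1.6
    metab = base.copy()
    for aa in "CLFTWY":
        metab[idx[aa]] *= 1.3
    return {
        "ribosome": ribo,
        "cytoplasm": metab.copy(),
        "membrane": metab.copy(),
        "protein_complex": base.copy(),
        "unannotated": base.copy(),
    }


@dataclass
class GrowthParams:
    """Dual-Monod batch growth parameters.

    Defaults emulate a fructose-fed heterotroph batch: mu_max 0.35 1/h,
    2 g/L fructose (2.13 gCOD/L), 0.05 gCDW/L inoculum.
    """

    mu_max: float = 0.35  # 1/h
    ks_c: float = 0.02  # gCOD/L
    ks_n: float = 0.0005  # gN/L (ammonium affinity is high)
    yield_c: float = 0.40  # gCDW/gCOD
    yield_n: float = 8.0  # gCDW/gN
    c0: float = 2.133  # gCOD/L (2 g/L fructose)
    n0: float | None = None  # gN/L; None -> set per limitation
    x0: float = 0.05  # gCDW/L
    od_per_cdw: float = 2.5  # OD600 per gCDW/L
    t_end: float = 16.0  # h
    sample_dt: float = 2.0  # h between observations
    dt: float = 0.01  # h integration step


@dataclass
class CompositionRules:
    """Linear composition observables as functions of growth rate.

    Nucleic-acid stain intensity rises with mu; the protein fraction of
    cell dry weight falls; carbohydrate and cell size rise; storage
    (PHA) intensity jumps under nitrogen-containing limitation.
    """

    na_intercept: float = 40.0  # A.U.
    na_slope: float = 300.0  # A.U. per (1/h)
    protein_intercept: float = 0.65  # g/gCDW
    protein_slope: float = 0.50  # g/gCDW per (1/h)
    carb_intercept: float = 0.05
    carb_slope: float = 0.20
    size_intercept: float = 1.0  # um
    size_slope: float = 1.5  # um per (1/h)
    pha_base: float = 30.0  # A.U.
    pha_limited_gain: float = 120.0  # added when limiting & N-limited/dual
    lipid_base: float = 20.0
    lipid_slope: float = 60.0


@dataclass
class CytoParams:
    """Lognormal mixture parameters for event-table simulation.

    ``meanlog``/``sdlog`` are natural-log location/scale per channel.
    """

    n_events: int = 20000
    doublet_fraction: float = 0.02
    damaged_fraction: float = 0.25  # SGPI panel
    pha_positive_fraction: float = 0.30  # BODIPY panel
    volume_ml: float = 0.075
    dilution: float = 1.0
    cell_fsc: tuple[float, float] = (5.5, 0.4)
    cell_ssc: tuple[float, float] = (5.0, 0.4)
    cell_bl1: tuple[float, float] = (6.9, 0.35)
    bl3_low: tuple[float, float] = (3.0, 0.4)
    bl3_high: tuple[float, float] = (7.0, 0.4)
    rl1_cell: tuple[float, float] = (6.5, 0.4)
    bodipy_neg_bl1: tuple[float, float] = (3.5, 0.4)
    bodipy_pos_bl1: tuple[float, float] = (7.0, 0.4)
    area_ratio_sd: float = 0.03  # lognormal sd of BL1-A/BL1-H for singlets


@dataclass
class SimConfig:
    """Full ground-truth parameterization of the synthetic study."""

    seed: int = 0
    n_proteins_per_component: int = 40
    components: tuple[str, ...] = (
        "ribosome",
        "cytoplasm",
        "membrane",
        "protein_complex",
        "unannotated",
    )
    aa_bias: dict[str, np.ndarray] = field(default_factory=_default_aa_bias)
    # growth-law allocation: phi_ribo(mu) = alloc_intercept + alloc_slope*mu
    alloc_intercept: float = 0.10
    alloc_slope: float = 0.50  # per (1/h)
    # split of the non-ribosomal share among remaining components
    component_split: dict[str, float] = field(
        default_factory=lambda: {
            "cytoplasm": 0.22,
            "membrane": 0.24,
            "protein_complex": 0.06,
            "unannotated": 0.48,
        }
    )
    mean_protein_length: float = 250.0
    length_sdlog: float = 0.30
    min_protein_length: int = 50
    psm_budget: int = 50_000
    shared_peptide_fraction: float = 0.10
    growth: GrowthParams = field(default_factory=GrowthParams)
    composition: CompositionRules = field(default_factory=CompositionRules)
    cytometry: CytoParams = field(default_factory=CytoParams)
    noise_cv: dict[str, float] = field(
        default_factory=lambda: {"default": 0.05}
    )

    def cv(self, observable: str) -> float:
        return self.noise_cv.get(observable, self.noise_cv.get("default", 0.0))

    def phi_ribo(self, mu: float) -> float:
        return self.alloc_intercept + self.alloc_slope * mu

    def validate(self) -> None:
        for comp in self.components:
            if comp not in self.aa_bias:
                raise ConfigError(f"component {comp!r} has no aa_bias vector")
            w = np.asarray(self.aa_bias[comp], dtype=float)
            if w.shape != (len(AA_ORDER),):
                raise ConfigError(f"aa_bias for {comp!r} is not 20-dimensional")
            if (w < 0).any() or w.sum() <= 0:
                raise ConfigError(f"aa_bias for {comp!r} must be >=0 with positive sum")
        for mu in (0.0, self.growth.mu_max):
            phi = self.phi_ribo(mu)
            if not 0.0 < phi < 1.0:
                raise ConfigError(f"phi_ribo({mu}) = {phi} outside (0, 1)")
            prot = self.composition.protein_intercept - self.composition.protein_slope * mu
            if not 0.0 <= prot <= 1.0:
                raise ConfigError(f"protein fraction {prot} at mu={mu} outside [0, 1]")
        if self.growth.ks_c <= 0 or self.growth.ks_n <= 0:
            raise ConfigError("half-saturation constants must be positive")
        if self.growth.x0 <= 0 or self.growth.c0 <= 0:
            raise ConfigError("initial biomass and substrate must be positive")
        for frac in (self.cytometry.damaged_fraction, self.cytometry.pha_positive_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("population fractions must lie in [0, 1]")
        if abs(sum(self.component_split.values()) - 1.0) > 1e-9:
            raise ConfigError("component_split must sum to 1")

    def rng(self, *tags: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed)] + [int(t) for t in tags])


# ---------------------------------------------------------------------------
# Proteome + ontology generation

#: Toy cellular-component ontology: the three reference roots with at
#: least two levels of is_a/part_of descendants each.
_TOY_TERMS: dict[str, tuple[str, str]] = {
    "GO:0110165": ("cellular anatomical entity", "cellular_component"),
    "GO:0005737": ("cytoplasm", "cellular_component"),
    "GO:0005829": ("cytosol", "cellular_component"),
    "GO:0016020": ("membrane", "cellular_component"),
    "GO:0005886": ("plasma membrane", "cellular_component"),
    "GO:0032991": ("protein-containing complex", "cellular_component"),
    "GO:1902494": ("catalytic complex", "cellular_component"),
    "GO:1905368": ("peptidase complex", "cellular_component"),
    "GO:0005840": ("ribosome", "cellular_component"),
    "GO:0022626": ("cytosolic ribosome", "cellular_component"),
    "GO:0022625": ("cytosolic large ribosomal subunit", "cellular_component"),
}

_TOY_EDGES: list[tuple[str, str, str]] = [
    ("GO:0005737", "GO:0110165", "is_a"),
    ("GO:0005829", "GO:0005737", "part_of"),
    ("GO:0016020", "GO:0110165", "is_a"),
    ("GO:0005886", "GO:0016020", "is_a"),
    ("GO:1902494", "GO:0032991", "is_a"),
    ("GO:1905368", "GO:1902494", "is_a"),
    ("GO:0005840", "GO:0032991", "is_a"),
    ("GO:0022626", "GO:0005840", "is_a"),
    ("GO:0022626", "GO:0005829", "part_of"),
    ("GO:0022625", "GO:0022626", "part_of"),
]

#: Leaf CC term each annotated component's proteins are assigned to.
_COMPONENT_TERM = {
    "ribosome": "GO:0022625",
    "cytoplasm": "GO:0005737",
    "membrane": "GO:0005886",
    "protein_complex": "GO:1905368",
}


def toy_go_graph() -> GoGraph:
    """The built-in toy cellular-component DAG."""
    return GoGraph.from_edges(_TOY_TERMS, _TOY_EDGES)


@dataclass
class SyntheticProteome:
    """Generated proteome with its component ground truth and ontology."""

    db: ProteinDB
    component_of: dict[str, str]
    graph: GoGraph
    annotations: dict[str, set[str]]

    def proteins_of(self, component: str) -> list[str]:
        return [p for p, c in self.component_of.items() if c == component]

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.db, out_dir / "proteome.fasta")
        write_obo(self.graph, out_dir / "ontology.obo")
        with open(out_dir / "annotations.tsv", "w") as fh:
            for pid in sorted(self.annotations):
                for go_id in sorted(self.annotations[pid]):
                    fh.write(f"{pid}\t{go_id}\n")
        with open(out_dir / "truth_components.tsv", "w") as fh:
            fh.write("protein_id\tcomponent\n")
            for pid in sorted(self.component_of):
                fh.write(f"{pid}\t{self.component_of[pid]}\n")


def simulate_proteome(config: SimConfig) -> SyntheticProteome:
    """Generate a proteome whose residues follow each component's AA bias.

    Protein lengths are lognormal around ``mean_protein_length``;
    annotated components map to one leaf CC term of the toy ontology;
    "unannotated" proteins receive no term.
    """
    config.validate()
    rng = config.rng(1)
    aas = np.array(list(AA_ORDER))
    records: list[ProteinRecord] = []
    component_of: dict[str, str] = {}
    annotations: dict[str, set[str]] = {}
    idx = 0
    for comp in config.components:
        weights = np.asarray(config.aa_bias[comp], dtype=float)
        p = weights / weights.sum()
        for _ in range(config.n_proteins_per_component):
            idx += 1
            pid = f"P{idx:05d}"
            length = max(
                config.min_protein_length,
                int(round(config.mean_protein_length * rng.lognormal(0.0, config.length_sdlog))),
            )
            seq = "".join(rng.choice(aas, size=length, p=p))
            records.append(ProteinRecord(protein_id=pid, sequence=seq))
            component_of[pid] = comp
            term = _COMPONENT_TERM.get(comp)
            if term is not None:
                annotations[pid] = {term}
    db = ProteinDB.from_records(records, source="synthetic")
    return SyntheticProteome(
        db=db,
        component_of=component_of,
        graph=toy_go_graph(),
        annotations=annotations,
    )


def write_obo(graph: GoGraph, path: str | Path) -> None:
    """Write a GoGraph as a minimal OBO 1.2 document."""
    parents: dict[str, list[tuple[str, str]]] = {}
    for child, parent, relation in graph.edges():
        parents.setdefault(child, []).append((relation, parent))
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-cc\n")
        for go_id in sorted(graph.terms):
            fh.write(f"\n[Term]\nid: {go_id}\nname: {graph.name(go_id)}\n")
            ns = graph.namespace(go_id)
            if ns:
                fh.write(f"namespace: {ns}\n")
            for relation, parent in sorted(parents.get(go_id, [])):
                if relation == "is_a":
                    fh.write(f"is_a: {parent} ! {graph.name(parent)}\n")
                else:
                    fh.write(f"relationship: {relation} {parent} ! {graph.name(parent)}\n")


# ---------------------------------------------------------------------------
# Batch growth simulation


@dataclass
class SampleSeries:
    """Time-indexed bioreactor observables with ground-truth columns."""

    data: pd.DataFrame
    limitation: Limitation

    def __len__(self) -> int:
        return len(self.data)

    def write(self, path: str | Path) -> None:
        self.data.assign(limitation=self.limitation).to_csv(path, index=False)


def _initial_nitrogen(g: GrowthParams, limitation: Limitation) -> float:
    """Initial ammonium-N chosen so the requested substrate runs out first."""
    n_matched = g.c0 * g.yield_c / g.yield_n  # N that exactly matches the C supply
    if limitation == "carbon":
        return 2.0 * n_matched
    if limitation == "nitrogen":
        return 0.5 * n_matched
    if limitation == "dual":
        return n_matched
    raise ConfigError(f"unknown limitation {limitation!r}")


def _monod_mu(g: GrowthParams, c: float, n: float) -> float:
    return g.mu_max * min(c / (g.ks_c + c), n / (g.ks_n + n))


def _integrate_batch(
    g: GrowthParams, n0: float, dt: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-step RK4 integration of the dual-Monod batch ODE."""

    def deriv(state: np.ndarray) -> np.ndarray:
        x, c, n = np.maximum(state, 0.0)
        mu = _monod_mu(g, c, n)
        dx = mu * x
        return np.array([dx, -dx / g.yield_c, -dx / g.yield_n])

    steps = int(round(g.t_end / dt))
    times = np.empty(steps + 1)
    out = np.empty((steps + 1, 3))
    state = np.array([g.x0, g.c0, n0], dtype=float)
    times[0] = 0.0
    out[0] = state
    for i in range(steps):
        k1 = deriv(state)
        k2 = deriv(state + dt / 2 * k1)
        k3 = deriv(state + dt / 2 * k2)
        k4 = deriv(state + dt * k3)
        state = state + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        state = np.maximum(state, 0.0)
        times[i + 1] = (i + 1) * dt
        out[i + 1] = state
    mu = np.array([_monod_mu(g, c, n) for _, c, n in out])
    return times, out[:, 0], out[:, 1], out[:, 2], mu


def simulate_batch(
    config: SimConfig, limitation: Limitation, dt: float | None = None
) -> SampleSeries:
    """Simulate one batch run under the requested substrate limitation.

    Growth follows mu = mu_max * min(C/(Ks_C+C), N/(Ks_N+N)); composition
    observables follow the config's linear rules in mu; multiplicative
    lognormal noise is applied per observable at the configured CV.  The
    ground-truth phase label is "abundant" while every limiting substrate
    exceeds 10x its half-saturation constant.
    """
    config.validate()
    g = config.growth
    if limitation not in _LIMITATION_TAG:
        raise ConfigError(f"unknown limitation {limitation!r}")
    n0 = g.n0 if g.n0 is not None else _initial_nitrogen(g, limitation)
    if n0 <= 0:
        raise ConfigError("initial nitrogen must be positive")
    dt = g.dt if dt is None else dt
    times, x, c, n, mu = _integrate_batch(g, n0, dt)

    # observation grid
    obs_t = np.arange(0.0, g.t_end + 1e-9, g.sample_dt)
    pick = np.searchsorted(times, obs_t)
    pick = np.clip(pick, 0, len(times) - 1)
    t_o, x_o, c_o, n_o, mu_o = times[pick], x[pick], c[pick], n[pick], mu[pick]

    comp = config.composition
    truth = {
        "cdw_g_l": x_o,
        "cod_g_l": c_o,
        "nh4_g_l": n_o,
        "od600": x_o * g.od_per_cdw,
        "protein_g_gcdw": comp.protein_intercept - comp.protein_slope * mu_o,
        "carbohydrate_g_gcdw": comp.carb_intercept + comp.carb_slope * mu_o,
        "na_au": comp.na_intercept + comp.na_slope * mu_o,
        "cell_size_um": comp.size_intercept + comp.size_slope * mu_o,
        "lipid_au": comp.lipid_base + comp.lipid_slope * mu_o,
    }

    # ground-truth phase: abundant while every limiting substrate > 10*Ks
    if limitation == "carbon":
        abundant = c_o > 10.0 * g.ks_c
    elif limitation == "nitrogen":
        abundant = n_o > 10.0 * g.ks_n
    else:
        abundant = (c_o > 10.0 * g.ks_c) & (n_o > 10.0 * g.ks_n)
    phase = np.where(abundant, "abundant", "limiting")

    pha = np.full_like(mu_o, comp.pha_base)
    if limitation in ("nitrogen", "dual"):
        pha = pha + comp.pha_limited_gain * (phase == "limiting")
    truth["pha_au"] = pha

    rng = config.rng(2, _LIMITATION_TAG[limitation])
    noisy: dict[str, np.ndarray] = {}
    for name, values in truth.items():
        cv = config.cv(name)
        if cv > 0:
            sigma = np.sqrt(np.log1p(cv * cv))
            factor = rng.lognormal(-sigma * sigma / 2.0, sigma, size=len(values))
            noisy[name] = values * factor
        else:
            noisy[name] = values.astype(float)

    df = pd.DataFrame({"time_h": t_o, **noisy})
    df["mu_true"] = mu_o
    df["phase_true"] = phase
    return SampleSeries(data=df, limitation=limitation)


# ---------------------------------------------------------------------------
# PSM table simulation


def component_shares(config: SimConfig, mu: float) -> dict[str, float]:
    """Ground-truth proteome mass share of every component at rate mu."""
    phi = config.phi_ribo(mu)
    if not 0.0 < phi < 1.0:
        raise ConfigError(f"phi_ribo({mu}) = {phi} outside (0, 1)")
    shares = {"ribosome": phi}
    for comp, frac in config.component_split.items():
        shares[comp] = (1.0 - phi) * frac
    return shares


def simulate_psm_tables(
    config: SimConfig,
    mus: Sequence[float],
    proteome: SyntheticProteome | None = None,
    noise: Literal["poisson", "off"] = "poisson",
) -> list[PsmTable]:
    """One PSM table per growth rate, following the allocation growth law.

    Expected per-protein counts are budget * s_p * L_p / sum_q s_q L_q
    with per-protein abundance s_p = share(component)/n_component, so
    that length-normalized counts recover the component mass shares
    exactly.  ``noise="poisson"`` draws integer counts; ``"off"`` emits
    the exact expectations (non-integer).  A configurable fraction of
    peptides is shared between two same-component proteins, carved so
    that the majority-evidence razor rule restores the generating
    assignment in the noise-free case.
    """
    config.validate()
    if config.psm_budget <= 0:
        raise ConfigError("total PSM budget must be positive")
    if proteome is None:
        proteome = simulate_proteome(config)
    db = proteome.db
    tables: list[PsmTable] = []
    for si, mu in enumerate(mus):
        shares = component_shares(config, mu)
        rng = config.rng(3, si)
        pids = sorted(db.records)
        n_comp = {
            comp: len(proteome.proteins_of(comp)) for comp in config.components
        }
        s = np.array(
            [shares[proteome.component_of[p]] / n_comp[proteome.component_of[p]] for p in pids]
        )
        lengths = np.array([db.length(p) for p in pids], dtype=float)
        expected = config.psm_budget * s * lengths / float((s * lengths).sum())
        if noise == "poisson":
            counts = rng.poisson(expected).astype(float)
        elif noise == "off":
            counts = expected.copy()
        else:
            raise ConfigError(f"unknown noise mode {noise!r}")

        # choose which proteins donate a shared peptide: the largest-count
        # proteins, paired with a clearly weaker same-component partner so
        # razor evidence resolves the share back to the donor
        share_rows: dict[str, tuple[str, float]] = {}
        n_shared = int(round(config.shared_peptide_fraction * len(pids)))
        if n_shared > 0:
            by_count = sorted(range(len(pids)), key=lambda i: (-expected[i], pids[i]))
            made = 0
            for i in by_count:
                if made >= n_shared:
                    break
                donor = pids[i]
                comp = proteome.component_of[donor]
                partners = [
                    j
                    for j, q in enumerate(pids)
                    if q != donor
                    and proteome.component_of[q] == comp
                    and expected[j] <= 0.4 * expected[i]
                ]
                if not partners or counts[i] < 5:
                    continue
                j = partners[int(rng.integers(len(partners)))]
                carved = np.floor(0.2 * counts[i]) if noise == "poisson" else 0.2 * counts[i]
                if carved < 1:
                    continue
                share_rows[donor] = (pids[j], float(carved))
                made += 1

        rows: list[PsmRow] = []
        for i, pid in enumerate(pids):
            total = counts[i]
            if total <= 0:
                continue
            if pid in share_rows:
                partner, carved = share_rows[pid]
                unique = total - carved
                if unique > 0:
                    rows.append(PsmRow(f"pep_{pid}", (pid,), unique))
                pair = tuple(sorted((pid, partner)))
                rows.append(PsmRow(f"pep_shared_{pid}", pair, carved))
            else:
                rows.append(PsmRow(f"pep_{pid}", (pid,), total))
        tables.append(PsmTable(sample_id=f"mu_{mu:.3f}", rows=rows))
    return tables


# ---------------------------------------------------------------------------
# Cytometry event simulation


def _lognormal(rng: np.random.Generator, param: tuple[float, float], n: int) -> np.ndarray:
    return rng.lognormal(param[0], param[1], size=n)


def _singlet_frame(config: SimConfig, panel: Panel, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cy = config.cytometry
    df = pd.DataFrame(
        {
            "FSC-H": _lognormal(rng, cy.cell_fsc, n),
            "SSC-H": _lognormal(rng, cy.cell_ssc, n),
        }
    )
    if panel == "BODIPY_SYTO62":
        pos = rng.random(n) < cy.pha_positive_fraction
        bl1 = np.where(
            pos,
            _lognormal(rng, cy.bodipy_pos_bl1, n),
            _lognormal(rng, cy.bodipy_neg_bl1, n),
        )
        df["BL1-H"] = bl1
        df["RL1-H"] = _lognormal(rng, cy.rl1_cell, n)
        df["BL3-H"] = _lognormal(rng, cy.bl3_low, n)
        df["population"] = np.where(pos, "pha_positive", "pha_negative")
    else:
        df["BL1-H"] = _lognormal(rng, cy.cell_bl1, n)
        df["RL1-H"] = _lognormal(rng, cy.rl1_cell, n)
        if panel == "SGPI":
            damaged = rng.random(n) < cy.damaged_fraction
            df["BL3-H"] = np.where(
                damaged,
                _lognormal(rng, cy.bl3_high, n),
                _lognormal(rng, cy.bl3_low, n),
            )
            df["population"] = np.where(damaged, "damaged", "intact")
        else:
            df["BL3-H"] = _lognormal(rng, cy.bl3_low, n)
            df["population"] = "cell"
    # area tracks height for singlets, with small acquisition noise
    df["BL1-A"] = df["BL1-H"] * rng.lognormal(0.0, cy.area_ratio_sd, n)
    return df


def simulate_events(config: SimConfig, panel: Panel) -> EventTable:
    """Simulate one stained-event table for the requested panel.

    Doublets are built from pairs of singlet draws: area channels are
    summed while height channels take the pair maximum plus 10%, so the
    area/height singlet gate can reject them.
    """
    config.validate()
    if panel not in _PANEL_TAG:
        raise ConfigError(f"unknown panel {panel!r}")
    cy = config.cytometry
    rng = config.rng(4, _PANEL_TAG[panel])
    n_doublets = int(round(cy.doublet_fraction * cy.n_events))
    n_singlets = cy.n_events - n_doublets
    singles = _singlet_frame(config, panel, n_singlets, rng)
    frames = [singles]
    if n_doublets > 0:
        a = _singlet_frame(config, panel, n_doublets, rng)
        b = _singlet_frame(config, panel, n_doublets, rng)
        doublet = pd.DataFrame(index=range(n_doublets))
        for col in ("FSC-H", "SSC-H", "BL1-H", "BL3-H", "RL1-H"):
            doublet[col] = np.maximum(a[col].to_numpy(), b[col].to_numpy()) * 1.1
        doublet["BL1-A"] = a["BL1-A"].to_numpy() + b["BL1-A"].to_numpy()
        doublet["population"] = "doublet"
        frames.append(doublet)
    events = pd.concat(frames, ignore_index=True)
    order = ["FSC-H", "SSC-H", "BL1-H", "BL1-A", "BL3-H", "RL1-H", "population"]
    events = events[order]
    return EventTable(
        events=events,
        volume_ml=cy.volume_ml,
        dilution=cy.dilution,
        panel=panel,
    )


# ---------------------------------------------------------------------------
# Whole-dataset convenience


def write_dataset(
    config: SimConfig,
    out_dir: str | Path,
    mus: Sequence[float] = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35),
    limitations: Iterable[Limitation] = ("carbon", "nitrogen", "dual"),
    panels: Iterable[Panel] = ("SG", "SGPI", "BODIPY_SYTO62"),
) -> None:
    """Generate and write every pipeline input under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    proteome = simulate_proteome(config)
    proteome.write(out_dir)
    tables = simulate_psm_tables(config, mus, proteome=proteome)
    write_psm_csv(tables, out_dir / "psm_tables.csv")
    for limitation in limitations:
        series = simulate_batch(config, limitation)
        series.write(out_dir / f"series_{limitation}.csv")
    for panel in panels:
        table = simulate_events(config, panel)
        write_events(table, out_dir / f"events_{panel}.csv")
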