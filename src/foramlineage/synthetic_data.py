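"""Synthetic stand-ins for the study's raw data.

Two generators: (a) two-lineage morphometric populations, emitted as raw
aperture geometry (widths, heights, flanking angles) so the downstream
PADR/SI computation is exercised end to end; (b) nucleotide alignments
evolved on a known tree under GTR+I+G, the oracle for topology and
parameter recovery.  A fixed 33-taxon tree of extant Globigerinoides,
relatives and three alternative outgroup sets mirrors the SSU rDNA
taxon sampling of the reference analysis.

All generators are bit-reproducible given a seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import Alignment, MeasurementTable, SequenceRecord, validate_measurements
from .phylo_model import GTRIGParams
from .phylo_inference import OutgroupScheme
from .tree import PhyloTree


# ---------------------------------------------------------------------------
# Morphometric populations
# ---------------------------------------------------------------------------

@dataclass
class MorphPopulationConfig:
    """Bivariate (PADR, SI) population emitted as raw aperture geometry.

    PADR/SI targets are drawn from a bivariate normal truncated to
    PADR > 0 and SI >= 1.  Raw geometry realizing each pair: aperture
    height uniform on (40, 120) um with width = PADR * height; smaller
    flanking angle uniform on (30, 80) degrees with larger = SI * smaller
    (redrawn while the larger angle would reach 180 degrees).  Which CSV
    column holds the larger angle is randomized per specimen.
    """

    group: str
    mean_padr: float
    sd_padr: float
    mean_si: float
    sd_si: float
    correlation: float = 0.0
    n: int = 200
    zone: str = "M3"
    sample_id: str = "synthetic"
    morphospecies: str = "synthetic sp."
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_padr <= 0 or self.sd_si <= 0:
            raise ValueError("standard deviations must be positive")
        if self.mean_si < 1:
            raise ValueError("mean_si is on the >= 1 scale")
        if not -1 < self.correlation < 1:
            raise ValueError("correlation must lie in (-1, 1)")
        if self.n < 0:
            raise ValueError("n must be >= 0")


def ruber_preset(**overrides) -> MorphPopulationConfig:
    """Low, tight PADR and SI near 1: high-arched symmetric apertures.

    The numeric defaults are calibration choices consistent with the
    qualitative description of the ruber lineage (low values of both
    indices, SI confined near [1, 1.5]); they are not measured values.
    """
    cfg = dict(
        group="ruber", mean_padr=0.9, sd_padr=0.15,
        mean_si=1.2, sd_si=0.1, correlation=0.2,
        morphospecies="G. subquadratus",
    )
    cfg.update(overrides)
    return MorphPopulationConfig(**cfg)


def trilobus_preset(**overrides) -> MorphPopulationConfig:
    """Higher, more variable PADR and SI: elongated slit-like apertures."""
    cfg = dict(
        group="trilobus", mean_padr=2.0, sd_padr=0.5,
        mean_si=2.0, sd_si=0.5, correlation=0.4,
        morphospecies='"G." trilobus',
    )
    cfg.update(overrides)
    return MorphPopulationConfig(**cfg)


def _draw_truncated_pairs(
    config: MorphPopulationConfig, rng: np.random.Generator
) -> np.ndarray:
    cov = np.array(
        [
            [config.sd_padr ** 2,
             config.correlation * config.sd_padr * config.sd_si],
            [config.correlation * config.sd_padr * config.sd_si,
             config.sd_si ** 2],
        ]
    )
    mean = np.array([config.mean_padr, config.mean_si])
    out = np.empty((0, 2))
    attempts = 0
    while len(out) < config.n:
        attempts += 1
        if attempts > 1000:
            raise ValueError(
                "could not draw enough (PADR, SI) pairs from the "
                "truncation region; configuration is infeasible"
            )
        draw = rng.multivariate_normal(mean, cov, size=max(config.n, 16))
        keep = draw[(draw[:, 0] > 0) & (draw[:, 1] >= 1)]
        out = np.vstack([out, keep])
    return out[: config.n]


def simulate_morphometrics(config: MorphPopulationConfig) -> MeasurementTable:
    """Generate a validated measurement table for one population."""
    rng = np.random.default_rng(config.seed)
    cols = {
        "specimen_id": [], "sample_id": [], "zone": [], "morphospecies": [],
        "width_um": [], "height_um": [], "angle1_deg": [], "angle2_deg": [],
        "lineage": [],
    }
    if config.n > 0:
        pairs = _draw_truncated_pairs(config, rng)
        for i, (padr, si) in enumerate(pairs):
            height = rng.uniform(40.0, 120.0)
            width = padr * height
            small = None
            for _ in range(1000):
                candidate = rng.uniform(30.0, 80.0)
                if si * candidate < 180.0:
                    small = candidate
                    break
            if small is None:
                raise ValueError(
                    f"cannot realize SI={si:.3f} with flanking angles below "
                    "180 degrees; configuration is infeasible"
                )
            large = si * small
            a1, a2 = (small, large) if rng.random() < 0.5 else (large, small)
            cols["specimen_id"].append(f"{config.group}-{config.zone}-{i:04d}")
            cols["sample_id"].append(config.sample_id)
            cols["zone"].append(config.zone)
            cols["morphospecies"].append(config.morphospecies)
            cols["width_um"].append(width)
            cols["height_um"].append(height)
            cols["angle1_deg"].append(a1)
            cols["angle2_deg"].append(a2)
            cols["lineage"].append(config.group)
    table = validate_measurements(pd.DataFrame(cols))
    if len(table.rejected):  # pragma: no cover - generator invariant
        raise AssertionError("generator emitted invalid rows")
    return table


# ---------------------------------------------------------------------------
# Sequence evolution on a tree
# ---------------------------------------------------------------------------

@dataclass
class SimTreeConfig:
    """Alignment simulation settings: generating tree + model + length."""

    tree: PhyloTree
    params: GTRIGParams = field(default_factory=GTRIGParams)
    n_sites: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


def simulate_alignment(config: SimTreeConfig) -> Alignment:
    """Evolve sequences along the tree under GTR+I+G.

    Root states are drawn from the stationary frequencies.  Each site
    draws its rate class once (invariant with probability p_inv,
    otherwise one of the k gamma categories uniformly) and keeps it on
    every edge, matching the +I+G likelihood's assumptions.
    """
    from .phylo_model import _Eigen, build_gtr_rate_matrix

    params = config.params
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    pi = params.base_freqs
    q = build_gtr_rate_matrix(params)
    eigen = _Eigen(q, pi)
    gamma_rates = params.rates()

    invariant = rng.random(n) < params.p_inv
    category = rng.integers(0, params.n_categories, size=n)
    site_rate = np.where(invariant, 0.0, gamma_rates[category])

    root_states = rng.choice(4, size=n, p=pi)
    states = {id(config.tree.root): root_states}
    for node in config.tree.preorder():
        if node is config.tree.root:
            continue
        t = node.length if node.length is not None else 0.0
        parent_states = states[id(node.parent)]
        child = parent_states.copy()
        if t > 0:
            for rate in np.unique(site_rate):
                if rate == 0.0:
                    continue
                mask = site_rate == rate
                pm = eigen.pmat(t * rate)
                rows = pm[parent_states[mask]]
                rows = rows / rows.sum(axis=1, keepdims=True)
                u = rng.random(mask.sum())
                child[mask] = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1)
        states[id(node)] = child

    bases = np.array(list("ACGT"))
    records = [
        SequenceRecord(leaf.name, "".join(bases[states[id(leaf)]]))
        for leaf in config.tree.leaves
    ]
    return Alignment(records)


# ---------------------------------------------------------------------------
# Reference taxon sampling and topology
# ---------------------------------------------------------------------------

INGROUP_TAXA = [
    "Globigerinoides_conglobatus_Z83967",
    "Sphaeroidinella_dehiscens_KM386666",
    "Globigerinoides_ruber_white_Ia_EU012458",
    "Globigerinoides_ruber_white_Ib2_EU012459",
    "Globigerinoides_ruber_pink_Z83966",
    "Globigerinoides_elongatus_IIa2_EU012452",
    "Globigerinoides_elongatus_IIa0_EU012463",
    "Globigerinoides_sacculifer_AB263459",
    "Globoturborotalita_rubescens_JQ799894",
    "Orbulina_universa_AF102229",
]

OUTGROUP1_TAXA = [
    "Beella_digitata_KF769946",
    "Globigerinella_siphonifera_Ia_Z83959",
    "Globigerinella_siphonifera_Ib_JQ743484",
    "Globigerinella_siphonifera_IIIa_KF769861",
    "Globigerinella_siphonifera_IIb_KF769820",
    "Globigerinella_siphonifera_IIa2_KF769629",
    "Globigerinella_siphonifera_IIa3_KF769634",
    "Globigerinella_siphonifera_IIa5_KF769785",
    "Globigerinella_siphonifera_IIa3_Z83960",
    "Globigerinella_siphonifera_IIa1_U80788",
]

OUTGROUP2_TAXA = [
    "Globigerina_bulloides_Ia_GQ293068",
    "Globigerina_bulloides_Ic_GQ293072",
    "Globigerina_bulloides_Ie_GU060421",
    "Globigerina_bulloides_Id_GQ293070",
    "Globigerina_bulloides_IIf_GQ293069",
    "Globigerina_bulloides_IIe_GQ293071",
    "Globigerina_bulloides_IIa_GU060422",
    "Globigerina_bulloides_IIb_AF250109",
    "Globigerina_bulloides_IId_AY241713",
    "Globigerina_falconensis_FJ643416",
]

OUTGROUP3_TAXA = [
    "Candeina_nitida_AB263435",
    "Globigerinita_glutinata_AB263433",
    "Globigerinita_uvula_FJ643302",
]

#: the ruber-group clade: ruber + elongatus + conglobatus + rubescens
RUBER_CLADE_TAXA = [
    "Globigerinoides_ruber_white_Ia_EU012458",
    "Globigerinoides_ruber_white_Ib2_EU012459",
    "Globigerinoides_ruber_pink_Z83966",
    "Globigerinoides_elongatus_IIa2_EU012452",
    "Globigerinoides_elongatus_IIa0_EU012463",
    "Globigerinoides_conglobatus_Z83967",
    "Globoturborotalita_rubescens_JQ799894",
]

#: the trilobus-group clade: sacculifer + Orbulina + Sphaeroidinella
TRILOBUS_CLADE_TAXA = [
    "Globigerinoides_sacculifer_AB263459",
    "Orbulina_universa_AF102229",
    "Sphaeroidinella_dehiscens_KM386666",
]


def outgroup_schemes() -> dict[str, OutgroupScheme]:
    """The three alternative outgroup rootings of the reference design:
    the sister lineage Globigerinella (plus Beella), the more distant
    spinose Globigerina, and the phylogenetically distant microperforate
    clade (Globigerinita + Candeina)."""
    return {
        "Outgroup 1": OutgroupScheme(
            "Outgroup 1", list(OUTGROUP1_TAXA), list(INGROUP_TAXA)
        ),
        "Outgroup 2": OutgroupScheme(
            "Outgroup 2", list(OUTGROUP2_TAXA), list(INGROUP_TAXA)
        ),
        "Outgroup 3": OutgroupScheme(
            "Outgroup 3", list(OUTGROUP3_TAXA), list(INGROUP_TAXA)
        ),
    }


def reference_topology_fixture(
    internal_length: float = 0.05, terminal_length: float = 0.1
) -> tuple[PhyloTree, dict[str, OutgroupScheme]]:
    """A 33-leaf tree carrying the two focal clades, plus the three
    outgroup schemes.

    The ingroup splits into the ruber group (ruber + elongatus +
    conglobatus clustering with Globoturborotalita rubescens) and the
    trilobus group (sacculifer with Orbulina and Sphaeroidinella); each
    outgroup set is monophyletic so that every scheme roots cleanly.
    """
    from .io_formats import parse_newick

    def cherry_chain(names: list[str]) -> str:
        out = names[0]
        for name in names[1:]:
            out = f"({out},{name})"
        return out

    ruber = (
        "((((Globigerinoides_ruber_white_Ia_EU012458,"
        "Globigerinoides_ruber_white_Ib2_EU012459),"
        "Globigerinoides_ruber_pink_Z83966),"
        "(Globigerinoides_elongatus_IIa2_EU012452,"
        "Globigerinoides_elongatus_IIa0_EU012463)),"
        "Globigerinoides_conglobatus_Z83967)"
    )
    ruber_clade = f"({ruber},Globoturborotalita_rubescens_JQ799894)"
    trilobus_clade = (
        "(Globigerinoides_sacculifer_AB263459,"
        "(Orbulina_universa_AF102229,Sphaeroidinella_dehiscens_KM386666))"
    )
    ingroup = f"({ruber_clade},{trilobus_clade})"
    og1 = f"({OUTGROUP1_TAXA[0]},{cherry_chain(OUTGROUP1_TAXA[1:])})"
    og2 = f"({cherry_chain(OUTGROUP2_TAXA[:9])},{OUTGROUP2_TAXA[9]})"
    og3 = f"({OUTGROUP3_TAXA[0]},({OUTGROUP3_TAXA[1]},{OUTGROUP3_TAXA[2]}))"
    newick = f"({ingroup},{og1},({og2},{og3}));"

    tree = parse_newick(newick)
    for node in tree.postorder():
        if node is tree.root:
            continue
        node.length = terminal_length if node.is_leaf else internal_length
    return tree, outgroup_schemes()
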