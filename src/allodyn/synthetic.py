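"""Synthetic inputs with known ground truth.

Every input the pipeline consumes can be generated here: harmonic Cα
ensembles with a prescribed residue-level correlation of motion,
dihedral fixtures, planted-community graphs, toy contact/H-bond
geometries, and operational-model concentration–response tables.

The harmonic ensemble draws, for each Cartesian axis independently, a
multivariate normal over residues with covariance sigma_i*sigma_j*C_ij.
Hence each residue's per-coordinate standard deviation is sigma_i, its
3-D RMSF converges to sqrt(3)*sigma_i, and the correlation of motion
C_ij = <dr_i·dr_j>/sqrt(<dr_i²><dr_j²>) equals the prescribed target
exactly in expectation — closed-form truth for the estimator tests.
Frames are i.i.d. (no autocorrelation) so persistency and correlation
estimators are unbiased; time correlation is deliberately not modelled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import DoseResponseDataset, Topology, Trajectory
from .network import DynamicalNetwork
from .pharm import OperationalParams, logistic3, operational_response

__all__ = [
    "HarmonicEnsembleSpec",
    "DoseResponseSimSpec",
    "gen_harmonic_trajectory",
    "gen_dihedral_fixture",
    "gen_planted_network",
    "two_clique_bridge",
    "gen_dose_response",
    "gen_logistic_dose_response",
    "ca_topology",
    "pair_distance_trajectory",
    "hbond_geometry_trajectory",
    "write_pdb",
    "write_dcd",
    "agonist_params",
    "CAMP_AGONIST_PANEL",
    "TRUPATH_POTENCIES",
    "CAMP_AGONIST_CONCENTRATIONS",
    "TRUPATH_AGONIST_CONCENTRATIONS",
    "MODULATOR_CONCENTRATIONS",
    "DEFAULT_NOISE_SD",
]


# ---------------------------------------------------------------------------
# Topology helpers


def ca_topology(
    n_residues: int,
    start_resid: int = 1,
    chain: str = "A",
    bw_map: dict[str, int] | None = None,
) -> Topology:
    """Cα-only poly-alanine topology with one atom per residue."""
    resids = np.arange(start_resid, start_resid + n_residues)
    return Topology(
        names=np.array(["CA"] * n_residues),
        elements=np.array(["C"] * n_residues),
        resids=resids,
        resnames=np.array(["ALA"] * n_residues),
        chains=np.array([chain] * n_residues),
        bw_map=bw_map,
    )


# ---------------------------------------------------------------------------
# Harmonic ensembles


@dataclass
class HarmonicEnsembleSpec:
    """Specification of a multi-replica harmonic Cα ensemble.

    ``per_residue_sigma`` is the per-coordinate standard deviation in Å;
    ``correlation_target`` the residue-level correlation of motion
    (symmetric, unit diagonal, entries in [−1, 1], positive semidefinite
    after scaling by the sigmas).
    """

    n_residues: int
    per_residue_sigma: np.ndarray
    correlation_target: np.ndarray
    n_frames: int
    n_replicas: int = 1
    seed: int = 0
    mean_structure: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.per_residue_sigma = np.broadcast_to(
            np.asarray(self.per_residue_sigma, dtype=float), (self.n_residues,)
        ).copy()
        self.correlation_target = np.asarray(self.correlation_target, dtype=float)
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if (self.per_residue_sigma <= 0).any():
            raise ValueError("per-residue sigma must be > 0")
        c = self.correlation_target
        if c.shape != (self.n_residues, self.n_residues):
            raise ValueError("correlation_target has wrong shape")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("correlation_target must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-12):
            raise ValueError("correlation_target diagonal must be exactly 1")
        if np.abs(c).max() > 1 + 1e-12:
            raise ValueError("correlation_target entries must lie in [-1, 1]")
        if self.mean_structure is None:
            # extended chain with the canonical Cα–Cα spacing
            self.mean_structure = np.zeros((self.n_residues, 3))
            self.mean_structure[:, 0] = 3.8 * np.arange(self.n_residues)
        else:
            self.mean_structure = np.asarray(self.mean_structure, dtype=float)
            if self.mean_structure.shape != (self.n_residues, 3):
                raise ValueError("mean_structure has wrong shape")

    def covariance(self) -> np.ndarray:
        s = self.per_residue_sigma
        return self.correlation_target * np.outer(s, s)


def _covariance_factor(cov: np.ndarray) -> np.ndarray:
    w, u = np.linalg.eigh(cov)
    tol = 1e-8 * max(1.0, float(w.max()))
    if w.min() < -tol:
        raise ValueError(
            "correlation target is not positive semidefinite after sigma scaling"
        )
    return u * np.sqrt(np.clip(w, 0.0, None))


def gen_harmonic_trajectory(spec: HarmonicEnsembleSpec) -> list[Trajectory]:
    """Draw i.i.d. harmonic frames about the mean structure, one Trajectory
    per replica.  Identical spec + seed gives bit-identical frames."""
    factor = _covariance_factor(spec.covariance())
    top = ca_topology(spec.n_residues)
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_replicas)
    out = []
    for replica, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        z = rng.standard_normal((spec.n_frames, 3, spec.n_residues))
        disp = z @ factor.T  # (frames, 3, residues)
        coords = spec.mean_structure[None, :, :] + disp.transpose(0, 2, 1)
        out.append(Trajectory(topology=top, coordinates=coords, replica=replica))
    return out


# ---------------------------------------------------------------------------
# Geometry fixtures


def gen_dihedral_fixture(angle: float) -> np.ndarray:
    """Four points whose A-B-C-D dihedral equals ``angle`` (degrees).

    180° gives the trans planar zig-zag, 0° the cis geometry.
    """
    if not (-180.0 < angle <= 180.0):
        raise ValueError("angle must lie in (-180, 180]")
    r = math.radians(angle)
    b = np.array([0.0, 0.0, 0.0])
    c = np.array([1.5, 0.0, 0.0])
    a = np.array([-0.5, 1.2, 0.0])
    d = c + np.array([0.5, 1.2 * math.cos(r), 1.2 * math.sin(r)])
    return np.stack([a, b, c, d])


def pair_distance_trajectory(distances: Sequence[float], sidechain: bool = False) -> Trajectory:
    """Two single-residue probes separated by a prescribed distance per frame.

    With ``sidechain=True`` each residue carries an extra pseudo-atom
    (CB) 1.5 Å behind its CA along the separation axis, so heavy-atom
    contact gating can be toggled purely by the CA–CA distance.
    """
    distances = np.asarray(distances, dtype=float)
    if sidechain:
        names = np.array(["CA", "CB", "CA", "CB"])
        elements = np.array(["C", "C", "C", "C"])
        resids = np.array([1, 1, 2, 2])
    else:
        names = np.array(["CA", "CA"])
        elements = np.array(["C", "C"])
        resids = np.array([1, 2])
    top = Topology(
        names=names,
        elements=elements,
        resids=resids,
        resnames=np.array(["ALA"] * len(names)),
        chains=np.array(["A"] * len(names)),
    )
    frames = []
    for d in distances:
        if sidechain:
            frames.append(
                [[0, 0, 0], [-1.5, 0, 0], [d, 0, 0], [d + 1.5, 0, 0]]
            )
        else:
            frames.append([[0, 0, 0], [d, 0, 0]])
    return Trajectory(topology=top, coordinates=np.array(frames, dtype=float))


def hbond_geometry_trajectory(
    da_distances: Sequence[float], dha_angles: Sequence[float]
) -> tuple[Trajectory, list[tuple[int, int]], list[int]]:
    """Donor–H–acceptor triad with prescribed geometry per frame.

    Returns the trajectory plus the donor (N, H) pair and acceptor list
    expected by the hydrogen-bond persistency operation.  The donor
    nitrogen sits at the origin with its hydrogen 1.0 Å along +x; the
    acceptor oxygen is placed so the D–A distance and D–H–A angle match
    the requested values.
    """
    da = np.asarray(da_distances, dtype=float)
    th = np.asarray(dha_angles, dtype=float)
    if da.shape != th.shape:
        raise ValueError("distance and angle sequences must have equal length")
    frames = []
    for d, theta in zip(da, th):
        rad = math.radians(theta)
        # acceptor along the direction making angle theta at H with H->D
        direction = np.array([-math.cos(rad), math.sin(rad), 0.0])
        # solve |H + r*direction| = d for r > 0 (H at unit distance from D)
        disc = direction[0] ** 2 + d**2 - 1.0
        if disc < 0:
            raise ValueError("requested geometry is unreachable")
        r = -direction[0] + math.sqrt(disc)
        acceptor = np.array([1.0, 0.0, 0.0]) + r * direction
        frames.append([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], list(acceptor)])
    top = Topology(
        names=np.array(["N", "H", "O"]),
        elements=np.array(["N", "H", "O"]),
        resids=np.array([1, 1, 2]),
        resnames=np.array(["ASN", "ASN", "SER"]),
        chains=np.array(["A", "A", "A"]),
    )
    traj = Trajectory(topology=top, coordinates=np.array(frames))
    return traj, [(0, 1)], [2]


# ---------------------------------------------------------------------------
# Planted-community graphs


def gen_planted_network(
    n_per_block: int,
    n_blocks: int,
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> DynamicalNetwork:
    """Planted-partition graph dressed as a dynamical network.

    Within-block edges appear with probability ``p_in`` and carry high
    correlation magnitudes (|C| in [0.5, 0.9]); between-block edges
    appear with probability ``p_out`` and carry low ones ([0.1, 0.4]).
    Ground-truth block labels are stored on the nodes under ``block``.
    """
    if n_per_block < 2 or n_blocks < 1:
        raise ValueError("need n_per_block >= 2 and n_blocks >= 1")
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("require p_in > p_out with both in [0, 1]")
    rng = np.random.default_rng(seed)
    n = n_per_block * n_blocks
    g = nx.Graph()
    for node in range(n):
        g.add_node(node, block=node // n_per_block)
    for i in range(n):
        for j in range(i + 1, n):
            same = g.nodes[i]["block"] == g.nodes[j]["block"]
            if rng.random() < (p_in if same else p_out):
                corr = rng.uniform(0.5, 0.9) if same else rng.uniform(0.1, 0.4)
                g.add_edge(i, j, corr=float(corr), weight=float(-math.log(corr)))
    return DynamicalNetwork(graph=g, condition=f"planted-{n_blocks}x{n_per_block}")


def two_clique_bridge(n_per_clique: int = 10, bridge_corr: float = 0.2) -> DynamicalNetwork:
    """Two cliques joined by a single weak bridge edge."""
    g = nx.Graph()
    for block in range(2):
        nodes = range(block * n_per_clique, (block + 1) * n_per_clique)
        for node in nodes:
            g.add_node(node, block=block)
        for i in nodes:
            for j in nodes:
                if i < j:
                    g.add_edge(i, j, corr=0.8, weight=-math.log(0.8))
    g.add_edge(
        n_per_clique - 1,
        n_per_clique,
        corr=bridge_corr,
        weight=-math.log(bridge_corr),
    )
    return DynamicalNetwork(graph=g, condition="two-clique-bridge")


# ---------------------------------------------------------------------------
# Concentration–response simulation
#
# Study conditions: agonist concentrations span 1 pM–1 uM for the cAMP
# accumulation assay and 10 pM–10 uM for the TRUPATH G-protein
# dissociation assay, with the modulator at 0 (vehicle), 10 nM, 100 nM,
# 1 uM and 10 uM; four replicates per curve.  Responses are on a
# 0–100 normalized scale and carry additive Gaussian noise whose default
# SD (8 response units) reproduces the replicate-to-replicate pEC50
# scatter of the published assays (per-replicate SD ≈ 0.15 log units,
# i.e. an SEM near 0.07 over four replicates).

CAMP_AGONIST_CONCENTRATIONS: np.ndarray = 10.0 ** np.arange(-12.0, -5.9, 0.5)
TRUPATH_AGONIST_CONCENTRATIONS: np.ndarray = 10.0 ** np.arange(-11.0, -4.9, 0.5)
MODULATOR_CONCENTRATIONS: tuple[float, ...] = (0.0, 1e-8, 1e-7, 1e-6, 1e-5)
DEFAULT_NOISE_SD: float = 8.0

#: Vehicle potencies (pEC50, −log10 M) and composite cooperativities
#: (Logαβ) of the A1R agonist panel with the PAM MIPS521, from published
#: cAMP accumulation assays.
CAMP_AGONIST_PANEL: dict[str, dict[str, float]] = {
    "adenosine": {"pec50_vehicle": 7.85, "logab": 1.30},
    "NECA": {"pec50_vehicle": 8.31, "logab": 1.17},
    "CPA": {"pec50_vehicle": 8.56, "logab": 1.35},
    "BnOCPA": {"pec50_vehicle": 7.76, "logab": 1.57},
}

#: Published TRUPATH potencies (pEC50) for Gαo-subtype dissociation,
#: keyed by (agonist, G-protein isoform, condition).
TRUPATH_POTENCIES: dict[tuple[str, str, str], float] = {
    ("adenosine", "Goa", "DMSO"): 7.63,
    ("adenosine", "Goa", "MIPS521"): 8.33,
    ("adenosine", "Gob", "DMSO"): 7.09,
    ("adenosine", "Gob", "MIPS521"): 8.66,
    ("BnOCPA", "Goa", "DMSO"): 7.40,
    ("BnOCPA", "Goa", "MIPS521"): 7.92,
    ("BnOCPA", "Gob", "DMSO"): 7.81,
    ("BnOCPA", "Gob", "MIPS521"): 7.65,
}


def agonist_params(
    agonist: str,
    em: float = 100.0,
    tau_a: float = 10.0,
    tau_b: float = 0.3,
    k_b: float = 1e-7,
) -> OperationalParams:
    """Operational-model truth for one panel agonist.

    The vehicle potency pins K_A through the agonism reduction
    EC50 = K_A/(1 + tau_A); cooperativity is carried entirely by beta
    (alpha = 1) so log10(αβ) equals the panel value.  tau_A = 10 makes
    the agonists full agonists, tau_B = 0.3 gives the modulator the weak
    direct agonism it shows on its own, and K_B = 100 nM is a mid-range
    modulator affinity consistent with clear potentiation only above
    10 nM.
    """
    row = CAMP_AGONIST_PANEL[agonist]
    k_a = 10.0 ** (-row["pec50_vehicle"]) * (1.0 + tau_a)
    return OperationalParams(
        em=em,
        tau_a=tau_a,
        tau_b=tau_b,
        k_a=k_a,
        k_b=k_b,
        alpha=1.0,
        beta=10.0 ** row["logab"],
        n=1.0,
    )


@dataclass
class DoseResponseSimSpec:
    """Specification of a simulated concentration–response surface."""

    true_parameters: OperationalParams
    agonist_concentrations: np.ndarray = field(
        default_factory=lambda: CAMP_AGONIST_CONCENTRATIONS.copy()
    )
    modulator_concentrations: Sequence[float] = MODULATOR_CONCENTRATIONS
    n_replicates: int = 4
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    agonist: str = "agonist"

    def __post_init__(self) -> None:
        self.agonist_concentrations = np.asarray(self.agonist_concentrations, dtype=float)
        if (self.agonist_concentrations <= 0).any():
            raise ValueError("agonist concentrations must be strictly positive")
        if any(b < 0 for b in self.modulator_concentrations):
            raise ValueError("modulator concentrations must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def gen_dose_response(spec: DoseResponseSimSpec) -> DoseResponseDataset:
    """Simulate responses on the operational-model surface plus i.i.d.
    Gaussian noise; reproducible under the given seed."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for rep in range(1, spec.n_replicates + 1):
        for b in spec.modulator_concentrations:
            mu = operational_response(
                spec.agonist_concentrations, b, spec.true_parameters
            )
            noise = rng.normal(0.0, spec.noise_sd, mu.shape) if spec.noise_sd else 0.0
            for a, y in zip(spec.agonist_concentrations, mu + noise):
                rows.append(
                    dict(
                        agonist=spec.agonist,
                        agonist_concentration=a,
                        modulator_concentration=b,
                        response=y,
                        replicate=rep,
                    )
                )
    return DoseResponseDataset(table=pd.DataFrame(rows))


def gen_logistic_dose_response(
    pec50: float,
    concentrations: np.ndarray,
    top: float = 100.0,
    bottom: float = 0.0,
    n_replicates: int = 4,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    agonist: str = "agonist",
) -> DoseResponseDataset:
    """Simulate vehicle-style data straight from a unit-slope logistic."""
    concentrations = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    mu = logistic3(np.log10(concentrations), bottom, top, pec50)
    for rep in range(1, n_replicates + 1):
        noise = rng.normal(0.0, noise_sd, mu.shape) if noise_sd else 0.0
        for a, y in zip(concentrations, mu + noise):
            rows.append(
                dict(
                    agonist=agonist,
                    agonist_concentration=a,
                    modulator_concentration=0.0,
                    response=y,
                    replicate=rep,
                )
            )
    return DoseResponseDataset(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Standard-format writers, so synthetic systems flow through the same
# readers as real data.


def write_pdb(topology: Topology, coordinates: np.ndarray, path: str | Path) -> Path:
    """Write a topology + one frame as a standard PDB file."""
    import MDAnalysis as mda

    path = Path(path)
    u = _as_universe(topology)
    u.atoms.positions = np.asarray(coordinates, dtype=np.float32)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))
    return path


def write_dcd(trajectory: Trajectory, path: str | Path) -> Path:
    """Write all frames of a trajectory to a DCD file."""
    import MDAnalysis as mda

    path = Path(path)
    u = _as_universe(trajectory.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), trajectory.n_atoms) as writer:
            for frame in trajectory.coordinates:
                u.atoms.positions = frame.astype(np.float32)
                writer.write(u.atoms)
    return path


def _as_universe(topology: Topology):
    import MDAnalysis as mda

    resids_unique, res_index = np.unique(topology.resids, return_inverse=True)
    u = mda.Universe.empty(
        topology.n_atoms,
        n_residues=len(resids_unique),
        atom_resindex=res_index,
        residue_segindex=np.zeros(len(resids_unique), dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("name", topology.names.tolist())
    u.add_TopologyAttr("elements", topology.elements.tolist())
    u.add_TopologyAttr("resid", resids_unique.tolist())
    first = [topology.resnames[np.flatnonzero(res_index == k)[0]] for k in range(len(resids_unique))]
    u.add_TopologyAttr("resname", first)
    u.add_TopologyAttr("chainIDs", topology.chains.tolist())
    return u
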