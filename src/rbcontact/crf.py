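"""Grid-structured conditional random field over residue-base pairs.

Every (protein position i, RNA position j) pair carries a binary variable
r_ij (contact / no contact) on an Np x Nr grid whose neighborhood is
N_ij = {(i±1, j), (i, j±1)}.  The local potential is

    U_ij(r, y) = w_f . f_ij(r_ij, y)  +  w_g . sum_{(k,l) in N_ij} g_ijkl(r_ij, r_kl, y)

and the local conditional is the two-state Gibbs form
Pr(r_ij = v | r_N, y) = exp(-U_ij[v]) / sum_v' exp(-U_ij[v']).

Three feature families are supported (the Kronecker order below is fixed and
shared by the training gradients):

* family 1 — coevolution only:      f = [r; r̄] ⊗ [1; m_ij]
* family 2 — coevolution + labels:  f = [r; r̄] ⊗ δ(a_i, b_j) ⊗ [1; m_ij]
* family 3 — labels only:           f = [r; r̄] ⊗ δ(a_i, b_j)

with the analogous g over [r_ij; r̄_ij] ⊗ [r_kl; r̄_kl] and the neighbor's
observations (m_kl, a_k, b_l).  δ(a, b) is the one-hot indicator of the
(grouped residue, base) pair, of length G·4 — 20·4 = 80 without grouping.
Target sequences are degapped, so δ never sees a gap.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .coevolution import (
    GroupingScheme,
    IDENTITY_GROUPING,
    MIMatrix,
    N_BASES,
    apc_correction,
    base_index,
    mutual_information,
)
from .alignments import PairedAlignmentSet
from .errors import AlphabetError


@dataclass
class ContactGrid:
    """Binary Np x Nr contact map (r_ij = 1 iff residue i touches base j)."""

    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r)
        if self.r.ndim != 2:
            raise ValueError("ContactGrid must be 2-D")
        if not np.isin(self.r, (0, 1)).all():
            raise ValueError("ContactGrid entries must be 0/1")
        self.r = self.r.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.r.shape

    def to_tsv(self, path: str | os.PathLike) -> None:
        np.savetxt(path, self.r, fmt="%d", delimiter="\t")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "ContactGrid":
        return cls(r=np.loadtxt(path, dtype=int, delimiter="\t", ndmin=2))


@dataclass(frozen=True)
class FeatureConfig:
    """Feature family plus amino-acid grouping; fixes parameter dimensions."""

    family: int = 1
    grouping: GroupingScheme = IDENTITY_GROUPING

    def __post_init__(self) -> None:
        if self.family not in (1, 2, 3):
            raise ValueError("family must be 1, 2 or 3")

    @property
    def label_size(self) -> int:
        """Length of the δ(a, b) indicator: (number of groups) · 4 bases."""
        return self.grouping.group_count * N_BASES

    @property
    def f_dim(self) -> int:
        if self.family == 1:
            return 4
        if self.family == 2:
            return 2 * self.label_size * 2
        return 2 * self.label_size

    @property
    def g_dim(self) -> int:
        if self.family == 1:
            return 8
        if self.family == 2:
            return 4 * self.label_size * 2
        return 4 * self.label_size


@dataclass
class CRFParams:
    """The parameter vectors (w_f, w_g) of a chosen feature configuration."""

    w_f: np.ndarray
    w_g: np.ndarray

    def __post_init__(self) -> None:
        self.w_f = np.asarray(self.w_f, dtype=float).ravel()
        self.w_g = np.asarray(self.w_g, dtype=float).ravel()

    @classmethod
    def zeros(cls, config: FeatureConfig) -> "CRFParams":
        return cls(w_f=np.zeros(config.f_dim), w_g=np.zeros(config.g_dim))

    def check(self, config: FeatureConfig) -> None:
        if len(self.w_f) != config.f_dim or len(self.w_g) != config.g_dim:
            raise ValueError(
                f"parameter lengths ({len(self.w_f)}, {len(self.w_g)}) do not "
                f"match feature dimensions ({config.f_dim}, {config.g_dim})"
            )

    def to_json(self, path: str | os.PathLike, config: FeatureConfig) -> None:
        payload = {
            "family": config.family,
            "grouping": config.grouping.name,
            "w_f": self.w_f.tolist(),
            "w_g": self.w_g.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> tuple["CRFParams", FeatureConfig]:
        with open(path) as fh:
            payload = json.load(fh)
        config = FeatureConfig(
            family=int(payload["family"]),
            grouping=GroupingScheme.from_name(int(payload["grouping"])),
        )
        params = cls(w_f=np.array(payload["w_f"]), w_g=np.array(payload["w_g"]))
        params.check(config)
        return params, config


@dataclass
class ProteinRNAInstance:
    """One training/test unit: target sequences, MI matrix, optional label grid."""

    a: str  # protein sequence, no gaps
    b: str  # RNA sequence, no gaps
    m: MIMatrix
    r: ContactGrid | None = None

    def __post_init__(self) -> None:
        n_p, n_r = self.m.shape
        if len(self.a) != n_p or len(self.b) != n_r:
            raise ValueError(
                f"MI matrix shape {self.m.shape} does not match sequence "
                f"lengths ({len(self.a)}, {len(self.b)})"
            )
        if self.r is not None and self.r.shape != (n_p, n_r):
            raise ValueError("contact grid shape does not match sequences")

    @property
    def shape(self) -> tuple[int, int]:
        return self.m.shape


def build_instance(
    paired: PairedAlignmentSet,
    grouping: GroupingScheme = IDENTITY_GROUPING,
    kind: str = "mi",
    contacts: ContactGrid | None = None,
) -> ProteinRNAInstance:
    """Assemble an instance from paired alignments: reference sequences + MI."""
    mi = mutual_information(paired, grouping)
    if kind == "mip":
        mi = apc_correction(mi)
    elif kind != "mi":
        raise ValueError(f"unknown MI kind {kind!r}")
    return ProteinRNAInstance(
        a=paired.protein.reference.residues,
        b=paired.rna.reference.residues,
        m=mi,
        r=contacts,
    )


def neighbors(i: int, j: int, n_p: int, n_r: int) -> list[tuple[int, int]]:
    """In-bounds grid neighbors of (i, j), in (up, down, left, right) order."""
    if not (0 <= i < n_p and 0 <= j < n_r):
        raise IndexError(f"cell ({i}, {j}) outside a {n_p}x{n_r} grid")
    out = []
    if i > 0:
        out.append((i - 1, j))
    if i < n_p - 1:
        out.append((i + 1, j))
    if j > 0:
        out.append((i, j - 1))
    if j < n_r - 1:
        out.append((i, j + 1))
    return out


def delta_vector(grouping: GroupingScheme, a: str, b: str) -> np.ndarray:
    """One-hot indicator of the (grouped residue, base) pair, length G·4."""
    vec = np.zeros(grouping.group_count * N_BASES)
    vec[grouping.index_of(a) * N_BASES + base_index(b, allow_gap=False)] = 1.0
    return vec


def _state(r: int) -> np.ndarray:
    if r not in (0, 1):
        raise ValueError("contact state must be 0 or 1")
    return np.array([float(r), float(1 - r)])


def feature_f(
    config: FeatureConfig, r_ij: int, m_ij: float, a_i: str | None = None, b_j: str | None = None
) -> np.ndarray:
    """Vertex feature vector f_ij for state r_ij."""
    state = _state(r_ij)
    if config.family == 1:
        return np.kron(state, [1.0, m_ij])
    if a_i is None or b_j is None:
        raise AlphabetError("families 2 and 3 need the residue and base labels")
    delta = delta_vector(config.grouping, a_i, b_j)
    if config.family == 2:
        return np.kron(np.kron(state, delta), [1.0, m_ij])
    return np.kron(state, delta)


def feature_g(
    config: FeatureConfig,
    r_ij: int,
    r_kl: int,
    m_kl: float,
    a_k: str | None = None,
    b_l: str | None = None,
) -> np.ndarray:
    """Edge feature vector g_ijkl; observations are the *neighbor's* (m_kl, a_k, b_l)."""
    pair = np.kron(_state(r_ij), _state(r_kl))
    if config.family == 1:
        return np.kron(pair, [1.0, m_kl])
    if a_k is None or b_l is None:
        raise AlphabetError("families 2 and 3 need the residue and base labels")
    delta = delta_vector(config.grouping, a_k, b_l)
    if config.family == 2:
        return np.kron(np.kron(pair, delta), [1.0, m_kl])
    return np.kron(pair, delta)


def _cell_potential(
    params: CRFParams,
    config: FeatureConfig,
    instance: ProteinRNAInstance,
    r: np.ndarray,
    i: int,
    j: int,
    value: int,
) -> float:
    """U_ij with r_ij set to ``value`` and neighbor states from the grid ``r``."""
    m = instance.m.values
    u = float(params.w_f @ feature_f(config, value, m[i, j], instance.a[i], instance.b[j]))
    for k, l in neighbors(i, j, *instance.shape):
        u += float(
            params.w_g
            @ feature_g(config, value, int(r[k, l]), m[k, l], instance.a[k], instance.b[l])
        )
    return u


def local_potential(
    params: CRFParams,
    config: FeatureConfig,
    instance: ProteinRNAInstance,
    r: ContactGrid | np.ndarray,
    i: int,
    j: int,
) -> float:
    """The potential U_ij(r, y) at the grid's own configuration."""
    grid = r.r if isinstance(r, ContactGrid) else np.asarray(r)
    return _cell_potential(params, config, instance, grid, i, j, int(grid[i, j]))


def local_conditional(
    params: CRFParams,
    config: FeatureConfig,
    instance: ProteinRNAInstance,
    r: ContactGrid | np.ndarray,
    i: int,
    j: int,
    value: int | None = None,
) -> float:
    """Pr(r_ij = value | neighbor states, observations), log-space stabilized.

    ``value`` defaults to the grid's own state at (i, j).
    """
    grid = r.r if isinstance(r, ContactGrid) else np.asarray(r)
    if value is None:
        value = int(grid[i, j])
    u0 = _cell_potential(params, config, instance, grid, i, j, 0)
    u1 = _cell_potential(params, config, instance, grid, i, j, 1)
    log_z = np.logaddexp(-u0, -u1)
    u = u1 if value == 1 else u0
    return float(np.exp(-u - log_z))
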