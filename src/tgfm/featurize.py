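"""Topology-augmented geometric feature encoder.

Pipeline: per-edge distances are mapped to high-dimensional features by a
learnable Gaussian basis; edge features are dispersed onto atoms by
destination-indexed mean aggregation (edge scatter); the resulting node
features are rescaled by a learnable per-degree, per-dimension scaler and
added to summed categorical atom embeddings.

Two augmentation variants are provided: per-edge-type affine modulation of
the distances before encoding, and gated fusion of the 3D (distance) and
2D (bond-embedding) channels.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, concat, gather_rows, segment_sum
from .layers import Embedding, Linear, Module
from .vocab import ATOM_FEATURE_DIMS, BOND_FEATURE_DIMS

SQRT_2PI = np.sqrt(2.0 * np.pi)


class GaussianBasis(Module):
    """Distance encoder: one learnable (mean, width) pair per dimension.

    phi_i(d) = exp(-((d - u_i) / sigma_i)^2 / 2) / sqrt(2 pi).

    The normaliser is the constant 1/sqrt(2 pi), independent of sigma, so
    every output lies in (0, 1/sqrt(2 pi)]; setting ``normalize_by_sigma``
    divides by sigma_i as the textbook density does.  Means start uniform
    over [0, 4] Angstrom (the covalent-bond range); widths start at 1 and
    stay positive because their logarithm is stored.
    """

    def __init__(self, dim: int, rng: np.random.Generator,
                 normalize_by_sigma: bool = False):
        self.u = Parameter(rng.uniform(0.0, 4.0, dim))
        self.log_sigma = Parameter(np.zeros(dim))
        object.__setattr__(self, "normalize_by_sigma", normalize_by_sigma)

    def __call__(self, D: Tensor) -> Tensor:
        """Encode distances (m,) into features (m, dim)."""
        if not np.all(np.isfinite(D.data)):
            raise ValueError("non-finite distance passed to Gaussian encoder")
        sigma = self.log_sigma.exp()
        z = (D.reshape(-1, 1) - self.u) / sigma
        phi = (z * z * -0.5).exp() * (1.0 / SQRT_2PI)
        if self.normalize_by_sigma:
            phi = phi / sigma
        return phi


def gauss_encode(D: np.ndarray | Tensor, basis: GaussianBasis) -> Tensor:
    D = D if isinstance(D, Tensor) else Tensor(D)
    return basis(D)


def edge_scatter(edge_feats: Tensor, EI: np.ndarray, n_atoms: int) -> Tensor:
    """Mean-aggregate edge features onto their destination atoms.

    With both bond directions stored, destination aggregation equals
    aggregation over chemical neighbours; atoms with no incident edge get
    the zero vector.
    """
    dst = np.asarray(EI[1], dtype=np.intp)
    if dst.size and (dst.min() < 0 or dst.max() >= n_atoms):
        raise ValueError("edge endpoint out of range")
    summed = segment_sum(edge_feats, dst, n_atoms)
    counts = np.bincount(dst, minlength=n_atoms).astype(np.float64)
    return summed * (1.0 / np.maximum(counts, 1.0))[:, None]


def degree_buckets(degrees: np.ndarray) -> np.ndarray:
    """Map degree to the 4 scaler columns: 1..4 -> 0..3, >4 clamps to 3,
    0 maps to 0 (those rows are bypassed anyway)."""
    return np.clip(np.asarray(degrees, dtype=np.int64), 1, 4) - 1


class DegreeScaler(Module):
    """Learnable N x 4 multiplicative rescaling keyed by degree bucket."""

    def __init__(self, dim: int):
        self.lam = Parameter(np.ones((dim, 4)))

    def __call__(self, Psi: Tensor, degrees: np.ndarray) -> Tensor:
        scale = gather_rows(self.lam.T, degree_buckets(degrees))
        bypass = (np.asarray(degrees) == 0).astype(np.float64)[:, None]
        # degree-0 rows pass through unscaled
        return Psi * (scale * (1.0 - bypass) + bypass)


def degree_scale(Psi: Tensor, degrees: np.ndarray, scaler: DegreeScaler) -> Tensor:
    return scaler(Psi, degrees)


def combine(A_feats: Tensor, Psi_prime: Tensor) -> Tensor:
    """Final node features F = A + Psi'."""
    if A_feats.shape != Psi_prime.shape:
        raise ValueError(f"shape mismatch {A_feats.shape} vs {Psi_prime.shape}")
    return A_feats + Psi_prime


class AtomEncoder(Module):
    """Summed categorical embeddings over the 9 atom-feature columns."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.tables = [Embedding(v, dim, rng) for v in ATOM_FEATURE_DIMS]

    def __call__(self, atom_codes: np.ndarray) -> Tensor:
        out = self.tables[0](atom_codes[:, 0])
        for c in range(1, len(self.tables)):
            out = out + self.tables[c](atom_codes[:, c])
        return out


class BondEncoder(Module):
    """Summed categorical embeddings over the 3 bond-feature columns
    (the 2D-topology edge channel)."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.tables = [Embedding(v, dim, rng) for v in BOND_FEATURE_DIMS]

    def __call__(self, bond_codes: np.ndarray) -> Tensor:
        out = self.tables[0](bond_codes[:, 0])
        for c in range(1, len(self.tables)):
            out = out + self.tables[c](bond_codes[:, c])
        return out


class EdgeTypeModulation(Module):
    """Per-edge-type affine transform of distances: D' = scale(t) * D + shift(t)."""

    def __init__(self, n_types: int):
        self.scale = Parameter(np.ones(n_types))
        self.shift = Parameter(np.zeros(n_types))

    def __call__(self, D: Tensor, T: np.ndarray) -> Tensor:
        T = np.asarray(T, dtype=np.intp)
        if T.size and (T.min() < 0 or T.max() >= self.scale.size):
            raise ValueError(f"edge-type id out of range [0, {self.scale.size})")
        return gather_rows(self.scale, T) * D + gather_rows(self.shift, T)


def modulate_distances(D: np.ndarray | Tensor, T: np.ndarray,
                       mod: EdgeTypeModulation) -> Tensor:
    D = D if isinstance(D, Tensor) else Tensor(D)
    return mod(D, T)


class FeatureFusion(Module):
    """Gated convex combination of the 2D and 3D channels.

    A linear map of the concatenated channels produces one logit per node;
    its logistic value w gives F = w * F2d + (1 - w) * F3d.  The gate is a
    single scalar per node (2N + 1 parameters), exposed for inspection.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        self.gate = Linear(2 * dim, 1, rng, bias=True)
        object.__setattr__(self, "last_weights", None)

    def __call__(self, F2d: Tensor, F3d: Tensor) -> Tensor:
        w = self.gate(concat([F2d, F3d], axis=-1)).sigmoid()
        object.__setattr__(self, "last_weights", w.data.copy())
        return w * F2d + (1.0 - w) * F3d


def fuse_features(F2d: Tensor, F3d: Tensor, fusion: FeatureFusion) -> Tensor:
    if F2d.shape != F3d.shape:
        raise ValueError("fusion inputs must have identical shapes")
    return fusion(F2d, F3d)


class FeatureEncoder(Module):
    """The full encoder, assembled per configuration flags.

    ``edge_source`` selects the edge channel: "distance" (Gaussian-encoded
    3D bond lengths), "bond" (categorical bond embeddings, 2D topology
    only) or "none" (atom embeddings alone).  The feature-fusion variant
    builds both channels and gates between them.
    """

    def __init__(self, cfg, rng: np.random.Generator):
        dim = cfg.embed_dim
        object.__setattr__(self, "cfg", cfg)
        if cfg.use_atom_features:
            self.atom_encoder = AtomEncoder(dim, rng)
        fusion = cfg.variant == "feature_fusion"
        if cfg.edge_source == "distance" or fusion:
            self.gauss = GaussianBasis(dim, rng, cfg.gauss_normalize_by_sigma)
        if cfg.edge_source == "bond" or fusion:
            self.bond_encoder = BondEncoder(dim, rng)
        if cfg.use_degree_scaler:
            self.scaler = DegreeScaler(dim)
        if cfg.variant == "edge_attributes":
            self.modulation = EdgeTypeModulation(cfg.n_edge_types)
        if fusion:
            self.fusion = FeatureFusion(dim, rng)

    def _channel(self, edge_feats: Tensor, A_feats: Tensor, EI: np.ndarray,
                 degrees: np.ndarray, n_atoms: int) -> Tensor:
        cfg = self.cfg
        if cfg.use_edge_scatter:
            Psi = edge_scatter(edge_feats, EI, n_atoms)
        else:
            Psi = Tensor(np.zeros((n_atoms, cfg.embed_dim)))
        if cfg.use_degree_scaler:
            Psi = self.scaler(Psi, degrees)
        return combine(A_feats, Psi)

    def __call__(self, A: np.ndarray, EI: np.ndarray, n_atoms: int,
                 D: np.ndarray | None = None, EA: np.ndarray | None = None,
                 T: np.ndarray | None = None) -> Tensor:
        cfg = self.cfg
        degrees = np.bincount(np.asarray(EI[1], dtype=np.intp), minlength=n_atoms)
        if cfg.use_atom_features:
            A_feats = self.atom_encoder(A)
        else:
            A_feats = Tensor(np.zeros((n_atoms, cfg.embed_dim)))
        if cfg.variant == "feature_fusion":
            F3d = self._channel(self.gauss(self._distances(D, T)), A_feats,
                                EI, degrees, n_atoms)
            F2d = self._channel(self.bond_encoder(EA), A_feats, EI, degrees, n_atoms)
            return self.fusion(F2d, F3d)
        if cfg.edge_source == "distance":
            return self._channel(self.gauss(self._distances(D, T)), A_feats,
                                 EI, degrees, n_atoms)
        if cfg.edge_source == "bond":
            return self._channel(self.bond_encoder(EA), A_feats, EI, degrees, n_atoms)
        return A_feats

    def _distances(self, D: np.ndarray | None, T: np.ndarray | None) -> Tensor:
        if D is None:
            raise ValueError("distance channel enabled but no distances in batch; "
                             "run compute_edge_distances first or disable gauss")
        Dt = Tensor(np.asarray(D, dtype=np.float64))
        if self.cfg.variant == "edge_attributes":
            if T is None:
                raise ValueError("edge-attribute variant needs edge-type ids; "
                                 "run compute_edge_types first")
            Dt = self.modulation(Dt, T)
        return Dt
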