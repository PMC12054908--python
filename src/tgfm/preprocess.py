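"""Preprocessing of packed datasets: per-edge Euclidean distances and
online-dictionary edge-type ids, with disk caching.

Distances are computed only for bonded edges listed in ``EI`` (no all-pairs
matrix), in the units the coordinates came in (Angstrom for SDF input);
normalisation is left to the learnable Gaussian basis.  Edge types are
assigned in first-seen order by joining the three bond-feature codes into a
string key, so ids depend on dataset order; the dictionary is persisted
with the cache and reused verbatim at inference, with unseen keys mapping
to a reserved unknown id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .molio import PackedDataset, load_packed, save_packed

log = logging.getLogger(__name__)


@dataclass
class EdgeTypeDictionary:
    """First-seen-order mapping from bond-code key (codes joined with '-')
    to consecutive integer ids starting at 0."""

    mapping: dict[str, int] = field(default_factory=dict)
    next_id: int = 0                      # the running type counter

    def lookup(self, key: str, frozen: bool = False) -> int:
        if key in self.mapping:
            return self.mapping[key]
        if frozen:
            return self.unknown_id
        self.mapping[key] = self.next_id
        self.next_id += 1
        return self.mapping[key]

    @property
    def n_types(self) -> int:
        return self.next_id

    @property
    def unknown_id(self) -> int:
        """Reserved id for keys unseen during fitting."""
        return self.next_id

    def to_json(self) -> dict:
        return {"mapping": self.mapping, "next_id": self.next_id}

    @classmethod
    def from_json(cls, data: dict) -> "EdgeTypeDictionary":
        return cls(mapping=dict(data["mapping"]), next_id=int(data["next_id"]))


def compute_edge_distances(ds: PackedDataset) -> PackedDataset:
    """Populate ``D`` (per-edge Euclidean distances) and ``SD`` (= ``SE``).

    Molecule-by-molecule: gather endpoint coordinates through the edge
    index and take the Euclidean norm of their difference.
    """
    if ds.P is None:
        raise ValueError("coordinates absent: distances require 3D input")
    parts = []
    for i in range(ds.n_molecules):
        a0, a1 = ds.SM[i], ds.SM[i + 1]
        e0, e1 = ds.SE[i], ds.SE[i + 1]
        Pm = ds.P[a0:a1]
        if np.any(~np.isfinite(Pm)):
            raise ValueError(f"non-finite coordinate in molecule {i}")
        EIm = ds.EI[:, e0:e1]
        Ps, Pe = Pm[EIm[0]], Pm[EIm[1]]
        parts.append(np.sqrt(((Ps - Pe) ** 2).sum(axis=1)))
    ds.D = np.concatenate(parts) if parts else np.zeros(0)
    ds.SD = ds.SE.copy()
    return ds


def compute_edge_types(
    ds: PackedDataset, dictionary: EdgeTypeDictionary | None = None,
    frozen: bool = False,
) -> tuple[PackedDataset, EdgeTypeDictionary]:
    """Populate ``T`` (first-seen-order edge-type ids) and ``ST`` (= ``SE``).

    Pass a fitted ``dictionary`` with ``frozen=True`` to reuse a training
    vocabulary at inference; unseen keys then map to its unknown id.
    """
    if ds.EA is None:
        raise ValueError("edge attributes absent")
    d = dictionary if dictionary is not None else EdgeTypeDictionary()
    T = np.empty(ds.EA.shape[0], dtype=np.int64)
    for e in range(ds.EA.shape[0]):
        key = "-".join(map(str, ds.EA[e].tolist()))
        T[e] = d.lookup(key, frozen=frozen)
    ds.T = T
    ds.ST = ds.SE.copy()
    return ds, d


def preprocess(ds: PackedDataset,
               dictionary: EdgeTypeDictionary | None = None,
               frozen: bool = False) -> tuple[PackedDataset, EdgeTypeDictionary]:
    """Distances + edge types in one pass."""
    if ds.P is not None:
        compute_edge_distances(ds)
    ds, d = compute_edge_types(ds, dictionary, frozen)
    return ds, d


def save_cache(ds: PackedDataset, dictionary: EdgeTypeDictionary,
               path: str | Path) -> None:
    save_packed(ds, path, edge_type_dict=dictionary.to_json())


def load_cache(path: str | Path) -> tuple[PackedDataset, EdgeTypeDictionary]:
    ds, dict_json = load_packed(path)
    if dict_json is None:
        raise ValueError(f"cache at {path} has no edge-type dictionary")
    return ds, EdgeTypeDictionary.from_json(dict_json)


def cache_roundtrip(ds: PackedDataset, path: str | Path) -> PackedDataset:
    """Preprocess with write-through caching.

    If a cache exists at ``path`` it is loaded and recomputation skipped;
    otherwise distances and edge types are computed and written.
    """
    path = Path(path)
    if path.with_suffix(".json").exists():
        log.info("cache hit at %s, skipping recomputation", path)
        cached, _ = load_cache(path)
        return cached
    if ds.P is not None:
        compute_edge_distances(ds)
    ds, d = compute_edge_types(ds)
    save_cache(ds, d, path)
    return ds
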