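"""Building-block similarity matrices and the distance transform.

Similarity backends score pairs of building blocks on a common [0, 2] scale
(the convention of shape+color "combo" scores, whose shape and pharmacophore
components each range 0-1).  The default backend is 2D Morgan-fingerprint
Tanimoto rescaled onto that range; a 3D multiconformer backend can be
registered under the same contract.  Distances are ``max_score - score``,
averaged with the transpose and zero-diagonal'd, because raw score matrices
from conformer-overlay tools are only approximately symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "DistanceMatrix",
    "tanimoto2d_matrix",
    "similarity_matrix",
    "to_distance",
    "register_backend",
    "get_backend",
    "available_backends",
    "MAX_COMBO_SCORE",
]

#: Maximum of the combined similarity score: shape and color each in [0, 1].
MAX_COMBO_SCORE = 2.0

_SYMMETRY_TOL = 1e-9


@dataclass
class DistanceMatrix:
    """Symmetric pairwise building-block distances for one position.

    ``values[i, j] = max_score - similarity(i, j)`` after symmetrization;
    entries lie in [0, 2] with a zero diagonal.
    """

    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = list(self.ids)
        self.validate()

    def validate(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")
        if not np.allclose(self.values, self.values.T, atol=_SYMMETRY_TOL):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=_SYMMETRY_TOL):
            raise ValueError("distance matrix diagonal is not zero")
        if self.values.min() < -_SYMMETRY_TOL or self.values.max() > MAX_COMBO_SCORE + 1e-6:
            raise ValueError("distance entries must lie in [0, 2]")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, keep_ids) -> "DistanceMatrix":
        """Square submatrix restricted to ``keep_ids`` (in that order)."""
        index = {b: i for i, b in enumerate(self.ids)}
        rows = [index[b] for b in keep_ids]
        return DistanceMatrix(list(keep_ids), self.values[np.ix_(rows, rows)])

    def rectangular(self, row_ids, col_ids) -> np.ndarray:
        """(len(row_ids), len(col_ids)) block of distances."""
        index = {b: i for i, b in enumerate(self.ids)}
        r = [index[b] for b in row_ids]
        c = [index[b] for b in col_ids]
        return self.values[np.ix_(r, c)]


def _morgan_fingerprints(smiles_list, radius: int = 3, n_bits: int = 2048):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fps = []
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparsable SMILES at index {i}: {smi!r}")
        fps.append(gen.GetFingerprint(mol))
    return fps


def tanimoto2d_matrix(smiles_list, radius: int = 3, n_bits: int = 2048) -> np.ndarray:
    """All-by-all Morgan Tanimoto similarity in [0, 1].

    Fingerprints use radius 3 (bonds); self-similarity is exactly 1 and the
    matrix is symmetric by construction.
    """
    fps = _morgan_fingerprints(smiles_list, radius=radius, n_bits=n_bits)
    n = len(fps)
    sim = np.ones((n, n))
    for i in range(n):
        if i + 1 < n:
            row = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1 :])
            sim[i, i + 1 :] = row
            sim[i + 1 :, i] = row
    return sim


class BackendUnavailableError(RuntimeError):
    """Requested similarity backend is not registered."""


# A backend maps a list of SMILES to an (n, n) score matrix on [0, 2].
_BACKENDS: dict[str, Callable[[list], np.ndarray]] = {}


def register_backend(name: str, fn: Callable[[list], np.ndarray]) -> None:
    """Register a similarity backend.

    The backend contract: ``fn(smiles_list)`` returns an (n, n) matrix of
    combined scores in [0, 2] with ``score(m, m)`` equal to the backend
    maximum (2.0).  Symmetry is only required up to backend tolerance; the
    distance transform symmetrizes.
    """
    _BACKENDS[name] = fn


def get_backend(name: str) -> Callable[[list], np.ndarray]:
    if name not in _BACKENDS:
        raise BackendUnavailableError(
            f"similarity backend {name!r} is not available; registered backends: "
            f"{sorted(_BACKENDS)}. The default 'morgan2d' backend runs anywhere."
        )
    return _BACKENDS[name]


def available_backends() -> list[str]:
    return sorted(_BACKENDS)


def _morgan2d_backend(smiles_list) -> np.ndarray:
    # Rescaled x2 so the 2D backend shares the [0, 2] combo-score range.
    return 2.0 * tanimoto2d_matrix(smiles_list)


register_backend("morgan2d", _morgan2d_backend)


def similarity_matrix(smiles_list, backend: str = "morgan2d") -> np.ndarray:
    """Score matrix on [0, 2] from a registered backend."""
    return get_backend(backend)(smiles_list)


def to_distance(
    similarity: np.ndarray,
    ids=None,
    max_score: float = MAX_COMBO_SCORE,
    tol: float = 1e-6,
) -> DistanceMatrix:
    """Transform a similarity matrix into a ``DistanceMatrix``.

    d = max_score - s, then averaged with its transpose, diagonal set to
    zero.  Scores above ``max_score + tol`` indicate a backend violating its
    contract and raise.
    """
    s = np.asarray(similarity, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError(f"similarity matrix must be square, got {s.shape}")
    if s.max() > max_score + tol:
        raise ValueError(
            f"similarity score {s.max():.6f} exceeds the backend maximum {max_score}"
        )
    d = max_score - s
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, max_score)
    if ids is None:
        ids = list(range(s.shape[0]))
    return DistanceMatrix(ids, d)
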