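"""Areal adjacency structures and intrinsic-CAR mathematics.

The intrinsic conditional autoregressive (CAR) prior on a per-area vector
``x`` with precision ``tau`` has improper density

    log p(x | tau) = (rank/2) * log(tau) - (tau/2) * sum_{i~j} (x_i - x_j)^2

where the sum runs over unordered pairs of adjacent areas, and
``rank = n_areas - n_components`` is the rank of the graph Laplacian.  The
prior is flat along the per-component constant directions, which is why
sum-to-zero constraints (per connected component) are imposed on the random
effects that carry it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "AreaGraph",
    "read_adjacency",
    "write_adjacency",
    "grid_graph",
    "car_log_density",
    "sample_car_field",
    "center_sum_to_zero",
]


@dataclass
class AreaGraph:
    """Symmetric areal adjacency with neighbour lists.

    Area order is fixed (GAL file order or construction order); every
    per-area vector in the package is index-aligned to ``area_ids``.
    """

    area_ids: list[str]
    neighbours: list[np.ndarray]
    n_components: int = field(init=False)
    component_labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.area_ids)) != len(self.area_ids):
            raise ValueError("duplicate area ids")
        self.neighbours = [np.asarray(nb, dtype=np.int64) for nb in self.neighbours]
        if len(self.neighbours) != self.n_areas:
            raise ValueError("neighbour list length does not match number of areas")
        for i, nb in enumerate(self.neighbours):
            if np.any(nb == i):
                raise ValueError(f"self-loop at area {self.area_ids[i]!r}")
            if nb.size and (nb.min() < 0 or nb.max() >= self.n_areas):
                raise ValueError(f"neighbour index out of range at area {self.area_ids[i]!r}")
            if len(np.unique(nb)) != nb.size:
                raise ValueError(f"repeated neighbour at area {self.area_ids[i]!r}")
        sets = [set(nb.tolist()) for nb in self.neighbours]
        for i, nb in enumerate(self.neighbours):
            for j in nb:
                if i not in sets[j]:
                    raise ValueError(
                        f"asymmetric adjacency: {self.area_ids[i]!r} lists "
                        f"{self.area_ids[int(j)]!r} but not vice versa"
                    )
        adj = self.adjacency_matrix()
        n_comp, labels = connected_components(adj, directed=False)
        self.n_components = int(n_comp)
        self.component_labels = labels.astype(np.int64)
        self._eig_cache: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def rank(self) -> int:
        """Rank of the graph Laplacian: n_areas - n_components."""
        return self.n_areas - self.n_components

    def edges(self) -> np.ndarray:
        """Unordered adjacent pairs as an (m, 2) array with i < j."""
        out = [(i, int(j)) for i, nb in enumerate(self.neighbours) for j in nb if i < j]
        return np.asarray(out, dtype=np.int64).reshape(-1, 2)

    def adjacency_matrix(self) -> sp.csr_matrix:
        empty = np.empty(0, dtype=np.int64)
        rows = np.concatenate(
            [np.full(nb.size, i, dtype=np.int64) for i, nb in enumerate(self.neighbours)]
            or [empty]
        )
        cols = np.concatenate(self.neighbours or [empty])
        data = np.ones(cols.size)
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n_areas, self.n_areas))

    def laplacian(self) -> sp.csr_matrix:
        """Graph Laplacian L = D - W (unit weights)."""
        adj = self.adjacency_matrix()
        deg = np.asarray(adj.sum(axis=1)).ravel()
        return sp.diags(deg).tocsr() - adj

    def _laplacian_eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached dense eigendecomposition of the Laplacian."""
        if self._eig_cache is None:
            lam, vec = np.linalg.eigh(self.laplacian().toarray())
            self._eig_cache = (lam, vec)
        return self._eig_cache

    def component_indicator(self) -> np.ndarray:
        """(n_components, n_areas) 0/1 matrix of component membership."""
        out = np.zeros((self.n_components, self.n_areas))
        out[self.component_labels, np.arange(self.n_areas)] = 1.0
        return out

    def index_of(self, area_id: str) -> int:
        try:
            return self.area_ids.index(area_id)
        except ValueError:
            raise KeyError(f"unknown area id {area_id!r}") from None


def read_adjacency(path) -> AreaGraph:
    """Read a GAL-dialect spatial weights file.

    Format: header line ``0 <n> <name> <name>``; then for each area a line
    ``<id> <k>`` followed by a line of ``k`` neighbour ids.  Asymmetric
    entries are rejected, never silently symmetrised.
    """
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{path}: empty GAL file")
    header = lines[0].split()
    if len(header) < 2:
        raise ValueError(f"{path}: malformed GAL header {lines[0]!r}")
    n = int(header[1])
    tokens = " ".join(lines[1:]).split()
    pos = 0
    ids: list[str] = []
    raw: dict[str, list[str]] = {}
    for _ in range(n):
        if pos + 2 > len(tokens) + 1:
            raise ValueError(f"{path}: truncated GAL body")
        area, k = tokens[pos], int(tokens[pos + 1])
        pos += 2
        if area in raw:
            raise ValueError(f"{path}: duplicate area id {area!r}")
        if pos + k > len(tokens):
            raise ValueError(f"{path}: truncated neighbour list for area {area!r}")
        raw[area] = tokens[pos : pos + k]
        pos += k
        ids.append(area)
    if pos != len(tokens):
        raise ValueError(f"{path}: trailing tokens after {n} areas")
    index = {a: i for i, a in enumerate(ids)}
    neighbours = []
    for a in ids:
        nb = []
        for b in raw[a]:
            if b not in index:
                raise ValueError(f"{path}: area {a!r} lists unknown neighbour {b!r}")
            nb.append(index[b])
        neighbours.append(np.asarray(nb, dtype=np.int64))
    return AreaGraph(area_ids=ids, neighbours=neighbours)


def write_adjacency(graph: AreaGraph, path) -> None:
    """Write an AreaGraph in the GAL dialect read by :func:`read_adjacency`."""
    with open(path, "w") as fh:
        fh.write(f"0 {graph.n_areas} areas areas\n")
        for i, a in enumerate(graph.area_ids):
            nb = graph.neighbours[i]
            fh.write(f"{a} {nb.size}\n")
            fh.write(" ".join(graph.area_ids[int(j)] for j in nb) + "\n")


def grid_graph(n_rows: int, n_cols: int, n_areas: int | None = None) -> AreaGraph:
    """Rectangular rook-adjacency grid, optionally trimmed to ``n_areas``.

    Areas are labelled ``a0001`` ... in row-major order; trimming removes the
    trailing cells, mirroring a study region that does not fill the bounding
    rectangle.
    """
    total = n_rows * n_cols
    keep = total if n_areas is None else int(n_areas)
    if not 0 < keep <= total:
        raise ValueError("n_areas must be in (0, n_rows*n_cols]")
    width = len(str(keep))
    ids = [f"a{i + 1:0{width}d}" for i in range(keep)]
    neighbours: list[list[int]] = [[] for _ in range(keep)]
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            if i >= keep:
                continue
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                j = rr * n_cols + cc
                if rr < n_rows and cc < n_cols and j < keep:
                    neighbours[i].append(j)
                    neighbours[j].append(i)
    return AreaGraph(area_ids=ids, neighbours=[np.asarray(nb) for nb in neighbours])


def _check_vector(x, graph: AreaGraph) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (graph.n_areas,):
        raise ValueError(f"vector length {x.shape} does not match n_areas={graph.n_areas}")
    return x


def car_log_density(x, tau: float, graph: AreaGraph) -> float:
    """Intrinsic CAR log-density up to an additive constant.

    Returns ``(rank/2) log tau - (tau/2) sum_{i~j} (x_i - x_j)^2`` with the
    sum over unordered adjacent pairs; rank = n_areas - n_components.
    """
    x = _check_vector(x, graph)
    if not tau > 0:
        raise ValueError("tau must be positive")
    e = graph.edges()
    pen = float(np.sum((x[e[:, 0]] - x[e[:, 1]]) ** 2)) if e.size else 0.0
    return 0.5 * graph.rank * np.log(tau) - 0.5 * tau * pen


def center_sum_to_zero(x, graph: AreaGraph) -> np.ndarray:
    """Subtract the per-connected-component mean from x."""
    x = _check_vector(x, graph)
    labels = graph.component_labels
    sums = np.bincount(labels, weights=x, minlength=graph.n_components)
    counts = np.bincount(labels, minlength=graph.n_components)
    return x - (sums / counts)[labels]


def sample_car_field(
    graph: AreaGraph,
    tau: float,
    seed: int | np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Draw from the intrinsic CAR constrained to sum to zero per component.

    The draw is the singular Gaussian with precision ``tau * L`` restricted
    to the orthogonal complement of the Laplacian null space, i.e. with
    covariance ``pinv(L) / tau``.  ``size`` draws are returned as an
    (size, n_areas) array; ``size=None`` returns a single vector.
    """
    if not tau > 0:
        raise ValueError("tau must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam, vec = graph._laplacian_eig()
    tol = 1e-9 * max(lam.max(initial=1.0), 1.0)
    pos = lam > tol
    m = size if size is not None else 1
    z = rng.standard_normal((m, int(pos.sum())))
    z = z / np.sqrt(tau * lam[pos])
    out = z @ vec[:, pos].T
    return out[0] if size is None else out
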