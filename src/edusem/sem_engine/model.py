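"""Declarative model specification and compilation to RAM matrices."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Path", "Covariance", "ModelSpec", "RAMMatrices", "compile_ram", "implied_moments"]


@dataclass(frozen=True)
class Path:
    """Directed edge ``source -> target`` (loading or regression)."""

    source: str
    target: str
    free: bool = True
    value: float = 0.0      # used when not free
    start: float | None = None
    label: str | None = None

    def default_label(self) -> str:
        return f"{self.target}~{self.source}"


@dataclass(frozen=True)
class Covariance:
    """Symmetric edge: variance (a == b) or covariance between residuals."""

    a: str
    b: str
    free: bool = True
    value: float = 0.0
    start: float | None = None
    label: str | None = None

    def default_label(self) -> str:
        x, y = sorted((self.a, self.b))
        return f"{x}~~{y}"


@dataclass(frozen=True)
class ModelSpec:
    """A latent-variable model: variables, directed paths, (co)variances.

    Variables not named in any ``Covariance`` receive a free (residual)
    variance automatically.  When ``mean_structure`` is on, every observed
    variable gets a free intercept and latent means are fixed at zero.
    Sharing a label across cells imposes an equality constraint.
    """

    name: str
    observed: tuple[str, ...]
    latent: tuple[str, ...] = ()
    paths: tuple[Path, ...] = ()
    covariances: tuple[Covariance, ...] = ()
    mean_structure: bool = False

    @property
    def variables(self) -> tuple[str, ...]:
        return self.observed + self.latent

    def free_labels(self) -> tuple[str, ...]:
        return compile_ram(self).free_labels

    def with_mean_structure(self, on: bool = True) -> "ModelSpec":
        return replace(self, mean_structure=on)

    def fix_parameter(self, label: str, value: float = 0.0) -> "ModelSpec":
        """Return a copy with every cell carrying `label` fixed at `value`."""
        hit = False
        paths, covs = [], []
        for e in self.paths:
            if (e.label or e.default_label()) == label:
                e = replace(e, free=False, value=value)
                hit = True
            paths.append(e)
        for c in self.covariances:
            if (c.label or c.default_label()) == label:
                c = replace(c, free=False, value=value)
                hit = True
            covs.append(c)
        if not hit:
            raise KeyError(f"no parameter labelled {label!r} in model {self.name!r}")
        return replace(self, paths=tuple(paths), covariances=tuple(covs))

    def add(self, *edges: Path | Covariance) -> "ModelSpec":
        paths = self.paths + tuple(e for e in edges if isinstance(e, Path))
        covs = self.covariances + tuple(e for e in edges if isinstance(e, Covariance))
        return replace(self, paths=paths, covariances=covs)

    def to_dict(self) -> dict:
        """Declarative document form (round-trips through YAML/JSON)."""

        def edge(e):
            out = {"free": e.free}
            if not e.free:
                out["value"] = e.value
            if e.start is not None:
                out["start"] = e.start
            if e.label is not None:
                out["label"] = e.label
            return out

        return {
            "name": self.name,
            "observed": list(self.observed),
            "latent": list(self.latent),
            "mean_structure": self.mean_structure,
            "paths": [{"source": p.source, "target": p.target, **edge(p)} for p in self.paths],
            "covariances": [{"a": c.a, "b": c.b, **edge(c)} for c in self.covariances],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelSpec":
        return cls(
            name=doc["name"],
            observed=tuple(doc["observed"]),
            latent=tuple(doc.get("latent", ())),
            mean_structure=bool(doc.get("mean_structure", False)),
            paths=tuple(
                Path(d["source"], d["target"], free=d.get("free", True),
                     value=d.get("value", 0.0), start=d.get("start"), label=d.get("label"))
                for d in doc.get("paths", ())
            ),
            covariances=tuple(
                Covariance(d["a"], d["b"], free=d.get("free", True),
                           value=d.get("value", 0.0), start=d.get("start"), label=d.get("label"))
                for d in doc.get("covariances", ())
            ),
        )

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        import yaml

        return cls.from_dict(yaml.safe_load(text))


@dataclass
class RAMMatrices:
    """Compiled RAM form: fixed parts plus a label -> cell map for free cells."""

    names: tuple[str, ...]           # observed first, then latent
    observed: tuple[str, ...]
    A0: np.ndarray                   # fixed directed paths
    S0: np.ndarray                   # fixed symmetric part
    m0: np.ndarray                   # fixed means/intercepts
    free_labels: tuple[str, ...]     # sorted; defines theta order
    cells: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    starts: dict[str, float | None] = field(default_factory=dict)
    mean_structure: bool = False

    @property
    def t(self) -> int:
        return len(self.names)

    @property
    def p(self) -> int:
        return len(self.observed)

    @property
    def n_free(self) -> int:
        return len(self.free_labels)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def materialize(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        A = self.A0.copy()
        S = self.S0.copy()
        m = self.m0.copy()
        for value, label in zip(theta, self.free_labels):
            for mat, i, j in self.cells[label]:
                if mat == "A":
                    A[i, j] = value
                elif mat == "S":
                    S[i, j] = value
                    S[j, i] = value
                else:
                    m[i] = value
        return A, S, m

    def n_moments(self) -> int:
        p = self.p
        return p * (p + 1) // 2 + (p if self.mean_structure else 0)

    def cell_is_exogenous(self, name: str) -> bool:
        """True if `name` has no incoming directed edge (free or fixed)."""
        i = self.index(name)
        if np.any(self.A0[i, :] != 0):
            return False
        return not any(
            mat == "A" and r == i for cells in self.cells.values() for mat, r, _ in cells
        )


def _check_acyclic(edges: list[tuple[str, str]], variables: tuple[str, ...]) -> None:
    # Kahn's algorithm over source -> target edges
    from collections import defaultdict, deque

    out = defaultdict(set)
    indeg = {v: 0 for v in variables}
    for s, t in edges:
        if t not in out[s]:
            out[s].add(t)
            indeg[t] += 1
    queue = deque(v for v in variables if indeg[v] == 0)
    seen = 0
    while queue:
        v = queue.popleft()
        seen += 1
        for w in out[v]:
            indeg[w] -= 1
            if indeg[w] == 0:
                queue.append(w)
    if seen != len(variables):
        cyclic = sorted(v for v in variables if indeg[v] > 0)
        raise ValueError(f"directed paths contain a cycle through {cyclic}")


def compile_ram(spec: ModelSpec) -> RAMMatrices:
    """Compile a :class:`ModelSpec` to RAM matrices with a parameter map.

    Fails on unknown variables, duplicate variable names, cyclic regressions,
    or a label shared between cells with conflicting fixed/free status.
    """
    variables = spec.variables
    if len(set(variables)) != len(variables):
        raise ValueError("duplicate variable names")
    index = {v: i for i, v in enumerate(variables)}
    t = len(variables)
    A0 = np.zeros((t, t))
    S0 = np.zeros((t, t))
    m0 = np.zeros(t)
    cells: dict[str, list[tuple[str, int, int]]] = {}
    starts: dict[str, float | None] = {}
    fixed_status: dict[str, bool] = {}

    def register(label: str, free: bool, cell: tuple[str, int, int], start: float | None) -> None:
        if label in fixed_status and fixed_status[label] != free:
            raise ValueError(f"label {label!r} used with conflicting free/fixed status")
        fixed_status[label] = free
        cells.setdefault(label, []).append(cell)
        if label in starts and start is not None and starts[label] is not None and starts[label] != start:
            raise ValueError(f"label {label!r} has conflicting start values")
        if start is not None or label not in starts:
            starts[label] = start

    edges = []
    for e in spec.paths:
        for v in (e.source, e.target):
            if v not in index:
                raise ValueError(f"unknown variable {v!r} in path {e.source}->{e.target}")
        i, j = index[e.target], index[e.source]
        edges.append((e.source, e.target))
        if e.free:
            register(e.label or e.default_label(), True, ("A", i, j), e.start)
        else:
            if e.label is not None and fixed_status.get(e.label):
                raise ValueError(f"label {e.label!r} used with conflicting free/fixed status")
            if e.label is not None:
                fixed_status[e.label] = False
            A0[i, j] = e.value
    _check_acyclic(edges, variables)

    covered = set()
    for c in spec.covariances:
        for v in (c.a, c.b):
            if v not in index:
                raise ValueError(f"unknown variable {v!r} in covariance {c.a}~~{c.b}")
        i, j = index[c.a], index[c.b]
        covered.add(frozenset((c.a, c.b)))
        if c.free:
            register(c.label or c.default_label(), True, ("S", i, j), c.start)
        else:
            if c.label is not None and fixed_status.get(c.label):
                raise ValueError(f"label {c.label!r} used with conflicting free/fixed status")
            if c.label is not None:
                fixed_status[c.label] = False
            S0[i, j] = S0[j, i] = c.value
    # default free variance for any variable without an explicit one
    for v in variables:
        if frozenset((v,)) not in covered:
            register(f"{v}~~{v}", True, ("S", index[v], index[v]), None)

    if spec.mean_structure:
        for v in spec.observed:
            register(f"{v}~1", True, ("m", index[v], -1), None)

    free_labels = tuple(sorted(label for label, free in fixed_status.items() if free))
    ram = RAMMatrices(
        names=variables,
        observed=spec.observed,
        A0=A0,
        S0=S0,
        m0=m0,
        free_labels=free_labels,
        cells={k: v for k, v in cells.items() if fixed_status[k]},
        starts={k: v for k, v in starts.items() if fixed_status[k]},
        mean_structure=spec.mean_structure,
    )
    return ram


def implied_moments(ram: RAMMatrices, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    """Model-implied covariance (and means, if enabled) of the observed variables.

    Raises on a singular (I - A), which signals a feedback loop or an
    inadmissible parameter point.
    """
    A, S, m = ram.materialize(np.asarray(theta, dtype=float))
    t = ram.t
    eye = np.eye(t)
    try:
        B = np.linalg.solve(eye - A, eye)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"(I - A) singular: {err}") from err
    sigma_all = B @ S @ B.T
    p = ram.p
    sigma = sigma_all[:p, :p]
    mu = (B @ m)[:p] if ram.mean_structure else None
    return sigma, mu
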