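"""Core data containers and I/O: expression matrices, marker panels, priors.

The model operates on a cells-by-genes matrix of marker-gene expression,
rescaled per gene to the unit interval (log1p then min-max).  A marker panel
declares the branching topology: K terminal lineages and, for every gene in
the panel, the branch(es) along which it behaves as a switch-like marker.
On every other branch the gene is treated as transient (a Gaussian pulse).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml


class ValidationError(ValueError):
    """Input data violates a model contract."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """N-cells x G-genes non-negative expression matrix.

    ``normalized`` marks the matrix as being on the model scale, i.e. the
    per-gene log1p + min-max scale produced by :func:`normalize` (real data)
    or sampled directly on that scale (synthetic data).
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    normalized: bool = False

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "cell_ids", [str(c) for c in self.cell_ids])
        object.__setattr__(self, "gene_ids", [str(g) for g in self.gene_ids])
        if vals.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n, g = vals.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValidationError(
                f"shape {vals.shape} inconsistent with {len(self.cell_ids)} "
                f"cell ids and {len(self.gene_ids)} gene ids"
            )
        bad = np.argwhere(np.isnan(vals))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"NaN entry at (cell={self.cell_ids[i]!r}, gene={self.gene_ids[j]!r})"
            )
        bad = np.argwhere(vals < 0)
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"negative entry {vals[i, j]} at "
                f"(cell={self.cell_ids[i]!r}, gene={self.gene_ids[j]!r})"
            )
        if len(set(self.gene_ids)) != g:
            dup = sorted({x for x in self.gene_ids if self.gene_ids.count(x) > 1})
            raise ValidationError(f"duplicate gene ids: {dup}")
        if len(set(self.cell_ids)) != n:
            warnings.warn("duplicate cell ids; suffixing to make them unique")
            seen: dict[str, int] = {}
            fixed = []
            for c in self.cell_ids:
                if c in seen:
                    seen[c] += 1
                    fixed.append(f"{c}.{seen[c]}")
                else:
                    seen[c] = 0
                    fixed.append(c)
            object.__setattr__(self, "cell_ids", fixed)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass(frozen=True)
class MarkerPanel:
    """Branching topology: K branches and the per-gene switch/pulse roles.

    ``marker_map`` maps gene id -> frozenset of 1-based branch indices on
    which the gene is a switch-like marker; the gene is transient on every
    other branch.  Genes with an empty branch set are transient everywhere
    (this arises from topology ablation).
    """

    K: int
    branch_names: list[str]
    marker_map: dict[str, frozenset[int]]

    def __post_init__(self):
        if self.K < 1:
            raise ValidationError("K must be >= 1")
        if len(self.branch_names) != self.K:
            raise ValidationError("branch_names length must equal K")
        mm = {g: frozenset(int(b) for b in bs) for g, bs in self.marker_map.items()}
        object.__setattr__(self, "marker_map", mm)
        for g, bs in mm.items():
            if any(b < 1 or b > self.K for b in bs):
                raise ValidationError(f"gene {g!r} marks branch outside 1..{self.K}")
        # an entirely empty panel is allowed as a degenerate case (prior
        # sampling with no expression data); otherwise every branch needs
        # at least one marker, and four per lineage are recommended
        if mm:
            for k in range(1, self.K + 1):
                n_k = sum(1 for bs in mm.values() if k in bs)
                if n_k == 0:
                    raise ValidationError(
                        f"branch {self.branch_names[k - 1]!r} has no marker gene"
                    )
                if n_k < 4:
                    warnings.warn(
                        f"branch {self.branch_names[k - 1]!r} has only {n_k} marker "
                        "gene(s); at least four per lineage are recommended"
                    )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.marker_map)

    def markers_of(self, branch: int) -> list[str]:
        return [g for g, bs in self.marker_map.items() if branch in bs]

    def switch_mask(self, gene_order: list[str]) -> np.ndarray:
        """(G, K) boolean: True where gene g is switch-like on branch k."""
        mask = np.zeros((len(gene_order), self.K), dtype=bool)
        for j, g in enumerate(gene_order):
            for k in self.marker_map.get(g, frozenset()):
                mask[j, k - 1] = True
        return mask

    def validate_against(self, m: ExpressionMatrix) -> None:
        missing = [g for g in self.marker_map if g not in m.gene_ids]
        if missing:
            raise ValidationError(f"panel genes absent from matrix: {missing}")


@dataclass(frozen=True)
class NormalPrior:
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValidationError("prior sd must be strictly positive")


@dataclass(frozen=True)
class BetaPrior:
    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValidationError("Beta hyperparameters must be strictly positive")


@dataclass(frozen=True)
class GammaPrior:
    shape: float
    rate: float

    def __post_init__(self):
        if self.shape <= 0 or self.rate <= 0:
            raise ValidationError("Gamma hyperparameters must be strictly positive")


def _default_gene_priors() -> dict[str, NormalPrior]:
    # Scales chosen for the [0,1]-normalized expression axis: switch
    # amplitude delta near 0.5 (2*delta spans the axis); steepness tau wide
    # enough to admit genuinely switch-like profiles; pulse width zeta of
    # order tens (pulse sd ~ 1/sqrt(2*zeta) ~ 0.1).  The pulse amplitude
    # eta shrinks toward zero (half-normal): a marker gene is, by the
    # definition of a marker, weakly expressed on the lineages it does not
    # mark — a diffuse eta prior lets off-branch pulses impersonate
    # activation curves and destroys branch assignment.
    return {
        "delta": NormalPrior(0.5, 0.5),  # truncated >= 0
        "tau": NormalPrior(0.0, 10.0),
        "eta": NormalPrior(0.0, 0.25),  # truncated >= 0 (half-normal)
        "zeta": NormalPrior(50.0, 25.0),  # truncated >= 0
    }


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the hierarchical priors.

    ``gene`` holds normal priors for the dynamics parameters (delta, tau,
    eta, zeta); amplitudes and widths are truncated at zero.  ``t0`` is the
    Beta prior on activation/midpoint times, ``phi`` the Gamma prior on
    per-gene dispersion, ``beta`` the (tight) normal prior on the two global
    dropout coefficients, and ``dirichlet_conc`` the symmetric Dirichlet
    concentration on lineage proportions (None -> 1/K).
    Per-gene overrides live in ``per_gene`` as {gene_id: {param: prior}}.
    """

    gene: dict[str, NormalPrior] = field(default_factory=_default_gene_priors)
    t0: BetaPrior = BetaPrior(2.0, 2.0)
    phi: GammaPrior = GammaPrior(2.0, 4.0)
    beta: NormalPrior = NormalPrior(0.0, 0.1)  # N(0, 0.01) variance convention
    dirichlet_conc: float | None = None
    per_gene: dict[str, dict[str, NormalPrior | BetaPrior]] = field(default_factory=dict)
    # Constrain switch steepness tau to be positive (markers activate along
    # the branches they mark).  This anchors the direction of pseudotime:
    # with sign-free tau the likelihood is exactly invariant under
    # t -> 1 - t, t0 -> 1 - t0, tau -> -tau.
    tau_positive: bool = True

    def gene_prior(self, param: str, gene_id: str | None = None) -> NormalPrior:
        if gene_id is not None and param in self.per_gene.get(gene_id, {}):
            return self.per_gene[gene_id][param]  # type: ignore[return-value]
        return self.gene[param]

    def t0_prior(self, gene_id: str | None = None) -> BetaPrior:
        if gene_id is not None and "t0" in self.per_gene.get(gene_id, {}):
            return self.per_gene[gene_id]["t0"]  # type: ignore[return-value]
        return self.t0

    def concentration(self, K: int) -> np.ndarray:
        c = self.dirichlet_conc if self.dirichlet_conc is not None else 1.0 / K
        if c <= 0:
            raise ValidationError("Dirichlet concentration must be positive")
        return np.full(K, float(c))


# ---------------------------------------------------------------------------
# I/O


def read_expression(
    path, format: str | None = None, transpose: bool = False
) -> ExpressionMatrix:
    """Read an expression matrix (cells as rows unless ``transpose``).

    Formats: ``csv``/``tsv`` (header of gene names, first column cell names),
    ``mtx`` (MatrixMarket with ``.rows``/``.cols`` sidecar name files), and
    ``h5ad`` (matrix in X, names in obs/var indices).  Inferred from the file
    suffix when ``format`` is None.
    """
    path = str(path)
    if format is None:
        suffix = path.rsplit(".", 1)[-1].lower()
        format = {"csv": "csv", "tsv": "tsv", "txt": "tsv", "mtx": "mtx", "h5ad": "h5ad"}.get(suffix)
        if format is None:
            raise ValidationError(f"cannot infer format from {path!r}")
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except FileNotFoundError:
            raise IOError(f"cannot read expression file {path!r}") from None
        if transpose:
            df = df.T
        return ExpressionMatrix(df.to_numpy(dtype=float), list(df.index), list(df.columns))
    if format == "mtx":
        from scipy.io import mmread

        try:
            mat = mmread(path)
        except FileNotFoundError:
            raise IOError(f"cannot read matrix file {path!r}") from None
        base = path[: -len(".mtx")] if path.endswith(".mtx") else path
        try:
            with open(base + ".rows") as fh:
                rows = [ln.strip() for ln in fh if ln.strip()]
            with open(base + ".cols") as fh:
                cols = [ln.strip() for ln in fh if ln.strip()]
        except FileNotFoundError as e:
            raise IOError(f"missing MTX sidecar name file: {e.filename!r}") from None
        vals = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        if transpose:
            vals, rows, cols = vals.T, cols, rows
        return ExpressionMatrix(vals, rows, cols)
    if format == "h5ad":
        import anndata as ad

        try:
            adata = ad.read_h5ad(path)
        except FileNotFoundError:
            raise IOError(f"cannot read h5ad file {path!r}") from None
        X = adata.X
        vals = np.asarray(X.todense() if hasattr(X, "todense") else X, dtype=float)
        return ExpressionMatrix(vals, list(adata.obs_names), list(adata.var_names))
    raise ValidationError(f"unknown expression format {format!r}")


def write_expression(m: ExpressionMatrix, path, format: str = "csv") -> None:
    sep = {"csv": ",", "tsv": "\t"}.get(format)
    if sep is None:
        raise ValidationError(f"unsupported output format {format!r}")
    m.to_frame().to_csv(path, sep=sep)


def normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Gene-wise min-max rescaling of log1p expression onto [0, 1].

    log1p keeps exact zeros at zero so they remain candidate dropout events.
    A constant gene column has zero range and maps to all-zeros (warned); it
    carries no dynamic information.
    """
    if m.normalized:
        raise ValidationError("matrix is already normalized")
    logged = np.log1p(m.values)
    lo = logged.min(axis=0)
    hi = logged.max(axis=0)
    rng = hi - lo
    const = rng == 0
    if const.any():
        names = [m.gene_ids[j] for j in np.flatnonzero(const)]
        warnings.warn(f"constant gene column(s) map to all-zeros: {names}")
    safe = np.where(const, 1.0, rng)
    out = (logged - lo) / safe
    out[:, const] = 0.0
    return replace(m, values=out, normalized=True)


def parse_marker_panel(path, m: ExpressionMatrix | None = None) -> MarkerPanel:
    """Parse a YAML/JSON marker-panel file.

    Schema: ``branches`` is the ordered list of branch names (order defines
    indices 1..K); ``markers`` maps gene id -> branch name or list of names.
    """
    path = str(path)
    try:
        with open(path) as fh:
            text = fh.read()
    except FileNotFoundError:
        raise IOError(f"cannot read marker panel {path!r}") from None
    spec = json.loads(text) if path.endswith(".json") else yaml.safe_load(text)
    return build_marker_panel(spec, m)


def build_marker_panel(spec: dict, m: ExpressionMatrix | None = None) -> MarkerPanel:
    if not isinstance(spec, dict) or "branches" not in spec or "markers" not in spec:
        raise ValidationError("marker panel needs 'branches' and 'markers' keys")
    branches = [str(b) for b in spec["branches"]]
    index = {b: k + 1 for k, b in enumerate(branches)}
    if len(index) != len(branches):
        raise ValidationError("duplicate branch names")
    marker_map: dict[str, frozenset[int]] = {}
    for gene, bs in spec["markers"].items():
        names = [bs] if isinstance(bs, str) else list(bs)
        ks = set()
        for b in names:
            if b not in index:
                raise ValidationError(f"unknown branch {b!r} for gene {gene!r}")
            ks.add(index[b])
        marker_map[str(gene)] = frozenset(ks)
    panel = MarkerPanel(len(branches), branches, marker_map)
    if m is not None:
        panel.validate_against(m)
    return panel


def write_marker_panel(panel: MarkerPanel, path) -> None:
    spec = {
        "branches": panel.branch_names,
        "markers": {
            g: [panel.branch_names[k - 1] for k in sorted(bs)]
            for g, bs in panel.marker_map.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(spec, fh, sort_keys=False)
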