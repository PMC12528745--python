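"""Interval type-2 Takagi-Sugeno kernel-weight generator.

Instead of learning every coefficient of a convolution kernel, each filter
is described by two meta-parameters ``(w, code)`` in [0, 1].  A nine-rule
interval type-2 (IT2) fuzzy inference system maps each normalized kernel
position to an intermediate pattern value ``Win_i``, and a cosine dispersion

    W_i = 3 * cos(pi * w * Win_i)

turns that pattern into the actual kernel coefficients.  The trainable
count per filter is therefore 2 regardless of kernel size (a 3x3x3 kernel
drops from 27 free coefficients to 2, a 92.6% reduction), which is what
makes gradient-free training of the whole extractor tractable.

The IT2 machinery is deliberately small: three triangular terms per
variable whose footprint of uncertainty comes from perturbing the support
halfwidth, a fixed 9-rule base over the Cartesian product of the input
terms, singleton consequents {L: 0.25, M: 0.50, H: 0.75}, min t-norm
firing intervals and Nie-Tan type reduction (the closed-form average of
lower and upper firing strengths).  The result is deterministic: the same
gene always yields bitwise-identical kernels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "IT2Triangular",
    "FuzzyRuleBase",
    "FilterGene",
    "KernelWeights",
    "KernelBank",
    "SUPPORTED_KERNEL_SIZES",
    "membership_interval",
    "infer_pattern",
    "weighting_func",
    "kernel_from_gene",
    "build_kernel_bank",
    "parameter_reduction",
]

#: Kernel element counts the generator accepts: 3x3, 5x5, 3x3x3, 7x7, 5x5x5.
SUPPORTED_KERNEL_SIZES = frozenset({9, 25, 27, 49, 125})

_EPS = 1e-12


@dataclass(frozen=True)
class IT2Triangular:
    """Symmetric triangular IT2 membership function on the [0, 1] universe.

    The upper and lower membership bounds share the peak (grade 1 there)
    and differ only in support halfwidth; the band between them is the
    footprint of uncertainty.
    """

    peak: float
    upper_halfwidth: float
    lower_halfwidth: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.peak <= 1.0):
            raise ValueError(f"peak must lie in [0, 1], got {self.peak}")
        if self.lower_halfwidth <= 0 or self.upper_halfwidth <= 0:
            raise ValueError("halfwidths must be positive")
        if self.lower_halfwidth >= self.upper_halfwidth:
            raise ValueError(
                "lower_halfwidth must be strictly smaller than upper_halfwidth "
                f"(got {self.lower_halfwidth} >= {self.upper_halfwidth})"
            )

    def membership(self, x) -> Tuple[np.ndarray, np.ndarray]:
        """Lower/upper membership grades at ``x`` (scalar or array)."""
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("membership input must be finite")
        dist = np.abs(x - self.peak)
        upper = np.maximum(0.0, 1.0 - dist / self.upper_halfwidth)
        lower = np.maximum(0.0, 1.0 - dist / self.lower_halfwidth)
        return lower, upper


def membership_interval(x: float, mf: IT2Triangular) -> Tuple[float, float]:
    """Evaluate one IT2 term at a scalar point, returning (lower, upper)."""
    lower, upper = mf.membership(x)
    return float(lower), float(upper)


def _default_terms(h: float = 0.5, delta: float = 0.1) -> Dict[str, IT2Triangular]:
    # Low/Mid/High at peaks 0, 0.5, 1 with full overlap; FOU from +-delta
    # on the support halfwidth.
    return {
        name: IT2Triangular(peak=peak, upper_halfwidth=h + delta, lower_halfwidth=h - delta)
        for name, peak in (("Low", 0.0), ("Mid", 0.5), ("High", 1.0))
    }


# Rule base: (Numin term, Code term) -> consequent category.  Exactly the
# 9 antecedent pairs of {Low, Mid, High}^2.
_RULES: Tuple[Tuple[Tuple[str, str], str], ...] = (
    (("Low", "Low"), "L"),
    (("Mid", "Low"), "M"),
    (("High", "Low"), "H"),
    (("Low", "Mid"), "H"),
    (("Mid", "Mid"), "M"),
    (("High", "Mid"), "L"),
    (("Low", "High"), "H"),
    (("Mid", "High"), "L"),
    (("High", "High"), "H"),
)

_CONSEQUENTS: Dict[str, float] = {"L": 0.25, "M": 0.50, "H": 0.75}


@dataclass(frozen=True)
class FuzzyRuleBase:
    """The 9-rule IT2 T-S rule base mapping (Numin, Code) to Numout."""

    terms: Mapping[str, IT2Triangular] = field(default_factory=_default_terms)
    rules: Tuple[Tuple[Tuple[str, str], str], ...] = _RULES
    consequents: Mapping[str, float] = field(default_factory=lambda: dict(_CONSEQUENTS))

    def __post_init__(self) -> None:
        if len(self.rules) != 9:
            raise ValueError(f"rule base must contain exactly 9 rules, got {len(self.rules)}")
        antecedents = {pair for pair, _ in self.rules}
        expected = {(a, b) for a in ("Low", "Mid", "High") for b in ("Low", "Mid", "High")}
        if antecedents != expected:
            raise ValueError("rule antecedents must cover {Low,Mid,High}^2 exactly once each")
        values = [self.consequents[c] for c in ("L", "M", "H")]
        if not (0.0 < values[0] < values[1] < values[2] < 1.0):
            raise ValueError("consequents must satisfy 0 < L < M < H < 1")

    @property
    def output_range(self) -> Tuple[float, float]:
        vals = list(self.consequents.values())
        return min(vals), max(vals)

    def to_config(self) -> Dict[str, object]:
        """Plain-dict form suitable for YAML serialization."""
        return {
            "terms": {
                name: {
                    "peak": t.peak,
                    "upper_halfwidth": t.upper_halfwidth,
                    "lower_halfwidth": t.lower_halfwidth,
                }
                for name, t in self.terms.items()
            },
            "rules": [
                {"numin": pair[0], "code": pair[1], "numout": cons}
                for pair, cons in self.rules
            ],
            "consequents": dict(self.consequents),
        }

    @classmethod
    def from_config(cls, cfg: Mapping[str, object]) -> "FuzzyRuleBase":
        terms = {
            name: IT2Triangular(**params)  # type: ignore[arg-type]
            for name, params in cfg["terms"].items()  # type: ignore[union-attr]
        }
        rules = tuple(
            ((r["numin"], r["code"]), r["numout"]) for r in cfg["rules"]  # type: ignore[index]
        )
        return cls(terms=terms, rules=rules, consequents=dict(cfg["consequents"]))  # type: ignore[arg-type]


_DEFAULT_RULEBASE = FuzzyRuleBase()


def default_rulebase() -> FuzzyRuleBase:
    return _DEFAULT_RULEBASE


def infer_pattern(numin, code: float, rulebase: FuzzyRuleBase | None = None):
    """Type-reduced IT2 T-S output for inputs in [0, 1].

    ``numin`` may be a scalar or an array (``code`` is a scalar); the nine
    firing intervals use the min t-norm and the crisp output is the
    Nie-Tan weighted average of the consequent singletons.  The result is
    always inside [min consequent, max consequent] = [0.25, 0.75].
    """
    rb = rulebase if rulebase is not None else _DEFAULT_RULEBASE
    numin_arr = np.asarray(numin, dtype=float)
    scalar = numin_arr.ndim == 0
    numin_arr = np.atleast_1d(numin_arr)
    if not np.all(np.isfinite(numin_arr)) or not math.isfinite(code):
        raise ValueError("infer_pattern inputs must be finite")
    if np.any(numin_arr < 0) or np.any(numin_arr > 1) or not (0.0 <= code <= 1.0):
        raise ValueError("infer_pattern inputs must lie in [0, 1]")

    # Memberships of numin for each term (vectorized) and of code (scalars).
    numin_mf = {name: t.membership(numin_arr) for name, t in rb.terms.items()}
    code_mf = {name: t.membership(code) for name, t in rb.terms.items()}

    num = np.zeros_like(numin_arr)
    den = np.zeros_like(numin_arr)
    for (numin_term, code_term), consequent in rb.rules:
        nl, nu = numin_mf[numin_term]
        cl, cu = code_mf[code_term]
        f_lower = np.minimum(nl, cl)
        f_upper = np.minimum(nu, cu)
        strength = 0.5 * (f_lower + f_upper)  # Nie-Tan reduction
        num += strength * rb.consequents[consequent]
        den += strength
    if np.any(den <= _EPS):
        raise ValueError(
            "degenerate input: no rule fires (all firing strengths are zero)"
        )
    s = num / den
    return float(s[0]) if scalar else s


@dataclass(frozen=True)
class FilterGene:
    """The (w, code) meta-parameter pair describing one filter.

    Both controls are dimensionless and clamped into [0, 1] on
    construction so optimizer round-off can never produce an invalid gene.
    """

    w: float
    code: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.w) and math.isfinite(self.code)):
            raise ValueError("FilterGene fields must be finite")
        object.__setattr__(self, "w", float(min(1.0, max(0.0, self.w))))
        object.__setattr__(self, "code", float(min(1.0, max(0.0, self.code))))


@dataclass(frozen=True)
class KernelWeights:
    """Ordered kernel coefficients W_1..W_n generated from one gene."""

    values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.n,):
            raise ValueError(f"expected {self.n} coefficients, got shape {values.shape}")
        if np.max(np.abs(values)) > 3.0 + 1e-12:
            raise ValueError("kernel coefficients must satisfy |W_i| <= 3")
        object.__setattr__(self, "values", values)


def weighting_func(
    gene: FilterGene, n: int, rulebase: FuzzyRuleBase | None = None
) -> KernelWeights:
    """Generate ``n`` kernel coefficients from a two-parameter gene.

    Position universe ``p_i = (i + 0.5) / n`` feeds the IT2 inference as
    Numin with the gene's ``code``; the type-reduced pattern is dispersed
    by ``W_i = 3 cos(pi * w * Win_i)``.  Deterministic by construction.
    """
    if n not in SUPPORTED_KERNEL_SIZES:
        raise ValueError(
            f"unsupported kernel element count {n}; expected one of "
            f"{sorted(SUPPORTED_KERNEL_SIZES)}"
        )
    positions = (np.arange(n) + 0.5) / n
    win = infer_pattern(positions, gene.code, rulebase)
    values = 3.0 * np.cos(np.pi * gene.w * win)
    return KernelWeights(values=values, n=n)


def kernel_from_gene(
    gene: FilterGene,
    shape: Tuple[int, ...] = (3, 3, 3),
    rulebase: FuzzyRuleBase | None = None,
) -> np.ndarray:
    """Generate a kernel and reshape it to the requested spatial shape."""
    n = int(np.prod(shape))
    return weighting_func(gene, n, rulebase).values.reshape(shape)


@dataclass(frozen=True)
class KernelBank:
    """Per-layer collections of generated kernels (the effective weights).

    ``layers[l]`` has shape ``(out_channels_l, *kernel_shape)``.  The same
    kernel is replicated across a filter's input channels, so one array
    per output channel is all the forward pass needs.
    """

    layers: Tuple[np.ndarray, ...]
    kernel_shape: Tuple[int, ...]

    @property
    def n_kernels(self) -> int:
        return sum(layer.shape[0] for layer in self.layers)


def build_kernel_bank(
    genes: Sequence[Sequence[FilterGene]],
    spec,
    rulebase: FuzzyRuleBase | None = None,
) -> KernelBank:
    """Expand per-layer genes into the full bank of convolution kernels.

    ``genes[l]`` must contain either one gene per output channel of layer
    ``l`` (untied) or exactly one gene (layer-tied mode, in which all the
    layer's filters share a kernel).  ``spec`` is a
    :class:`gliofuzz.fcnn3d.NetworkSpec`.
    """
    if len(genes) != len(spec.channels):
        raise ValueError(
            f"gene list covers {len(genes)} layers but the network has "
            f"{len(spec.channels)}"
        )
    kshape = tuple(spec.kernel_shape)
    n = int(np.prod(kshape))
    layers: List[np.ndarray] = []
    for layer_idx, (layer_genes, out_ch) in enumerate(zip(genes, spec.channels)):
        if len(layer_genes) == 1:
            kernel = kernel_from_gene(layer_genes[0], kshape, rulebase)
            stack = np.broadcast_to(kernel, (out_ch, *kshape)).copy()
        elif len(layer_genes) == out_ch:
            stack = np.stack(
                [kernel_from_gene(g, kshape, rulebase) for g in layer_genes]
            )
        else:
            raise ValueError(
                f"layer {layer_idx}: got {len(layer_genes)} genes for "
                f"{out_ch} output channels (need {out_ch}, or 1 if layer-tied)"
            )
        layers.append(stack)
    bank = KernelBank(layers=tuple(layers), kernel_shape=kshape)
    assert bank.n_kernels == sum(spec.channels)
    # n recorded for the audit trail: every coefficient came from a 2-scalar gene
    assert all(layer.shape[1:] == kshape for layer in bank.layers), n
    return bank


def parameter_reduction(n: int) -> float:
    """Fraction of per-filter coefficients removed by the generator.

    A kernel with ``n`` native coefficients is controlled by 2 scalars,
    so the reduction is ``(n - 2) / n`` (92.59...% for n = 27).
    """
    if n not in SUPPORTED_KERNEL_SIZES:
        raise ValueError(f"unsupported kernel element count {n}")
    return (n - 2) / n
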