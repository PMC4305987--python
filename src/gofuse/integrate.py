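"""Type-conditional addition model combining seed-measure RankSims.

For a gene pair with seed group type t and member RankSim values V:

    Sim = sum_i w[t][i] * V_i  +  alpha[t]*max(V) + beta[t]*min(V)
          + gamma[t]*mean(V)

One weight exists per candidate measure per type (seed sets vary per
pair, so weights live at the candidate-measure level); weights of
measures outside a pair's seed group simply contribute nothing to that
pair.  Per type all parameters are non-negative and sum to 1, which
keeps Sim inside [min(V), max(V)] ⊆ [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

GROUP_TYPES = ("high", "low", "mix")

#: names of the three aggregate parameters, in vector order after the weights
EXTRAS = ("alpha", "beta", "gamma")

SUM_TOL = 1e-9


class ParameterError(ValueError):
    """Parameter vector violates non-negativity or the sum-to-one constraint."""


@dataclass
class ParameterSet:
    """Per-type weight vectors of the addition model.

    ``values[t]`` is a vector of length ``len(measures) + 3`` laid out
    as one weight per candidate measure followed by (alpha, beta, gamma).
    """

    measures: tuple
    values: dict

    def __post_init__(self):
        self.measures = tuple(self.measures)
        self.values = {t: np.asarray(v, dtype=float) for t, v in self.values.items()}

    @property
    def n_params(self) -> int:
        return len(self.measures) + 3

    def weight(self, group_type: str, measure: str) -> float:
        return float(self.values[group_type][self.measures.index(measure)])

    def extra(self, group_type: str, name: str) -> float:
        return float(self.values[group_type][len(self.measures) + EXTRAS.index(name)])

    def alpha(self, t: str) -> float:
        return self.extra(t, "alpha")

    def beta(self, t: str) -> float:
        return self.extra(t, "beta")

    def gamma(self, t: str) -> float:
        return self.extra(t, "gamma")

    def validate(self) -> None:
        for t in GROUP_TYPES:
            if t not in self.values:
                raise ParameterError(f"missing parameters for type {t!r}")
            v = self.values[t]
            if v.shape != (self.n_params,):
                raise ParameterError(
                    f"type {t!r}: expected {self.n_params} parameters, got {v.shape}"
                )
            if (v < 0).any():
                raise ParameterError(f"type {t!r}: negative parameter")
            if abs(v.sum() - 1.0) > SUM_TOL:
                raise ParameterError(f"type {t!r}: parameters sum to {v.sum()!r}, not 1")

    # -- constructors -----------------------------------------------------

    @classmethod
    def degenerate(cls, measures, extra: str) -> "ParameterSet":
        """All mass on one aggregate (``alpha``/``beta``/``gamma``) for every
        type; ``gamma`` gives plain mean-of-seed-RankSims integration."""
        k = len(measures)
        vec = np.zeros(k + 3)
        vec[k + EXTRAS.index(extra)] = 1.0
        return cls(tuple(measures), {t: vec.copy() for t in GROUP_TYPES})

    @classmethod
    def random(cls, measures, rng) -> "ParameterSet":
        """Symmetric Dirichlet(1) draw over each type's simplex."""
        k = len(measures) + 3
        return cls(tuple(measures), {t: rng.dirichlet(np.ones(k)) for t in GROUP_TYPES})

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        out = {}
        for t in GROUP_TYPES:
            v = self.values[t]
            out[t] = {
                "measure_weights": {
                    m: float(v[i]) for i, m in enumerate(self.measures)
                },
                "alpha": float(v[len(self.measures)]),
                "beta": float(v[len(self.measures) + 1]),
                "gamma": float(v[len(self.measures) + 2]),
            }
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        measures = tuple(sorted(data[GROUP_TYPES[0]]["measure_weights"]))
        values = {}
        for t in GROUP_TYPES:
            block = data[t]
            vec = [block["measure_weights"][m] for m in measures]
            vec += [block["alpha"], block["beta"], block["gamma"]]
            values[t] = np.array(vec, dtype=float)
        ps = cls(measures, values)
        ps.validate()
        return ps

    @classmethod
    def load(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def integrate(pair_values: dict, group, params: ParameterSet) -> float:
    """Apply the addition model to one gene pair.

    *pair_values* maps measure name -> RankSim; *group* supplies the
    seed members and the type selecting which parameter vector applies.
    """
    params.validate()
    missing = [m for m in group.members if m not in pair_values]
    if missing:
        raise KeyError(f"seed members without values: {missing}")
    t = group.group_type
    v = np.array([pair_values[m] for m in group.members], dtype=float)
    total = sum(
        params.weight(t, m) * pair_values[m] for m in group.members
    )
    total += params.alpha(t) * v.max()
    total += params.beta(t) * v.min()
    total += params.gamma(t) * v.mean()
    return float(total)
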