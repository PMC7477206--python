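"""Structural-equation model specification.

A model is a set of observed variables, latent variables with ordered
indicator lists, free directed paths among structural variables, free
covariances (including exogenous ones such as age with the CVR score),
correlated-residual pairs among indicators, and a ``fixed`` map pinning
any parameter to a constant (unit-loading markers, zero-constrained
paths).

Parameters are keyed by ``(kind, a, b)`` with kinds ``'loading'``
(latent, indicator), ``'path'`` (source, target), ``'var'`` (variable,
variable) for an exogenous or residual variance, and ``'cov'`` (a, b).
The parameter order is deterministic, which fixes the layout of the free
parameter vector theta.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence, Tuple

from ..schema import GM_COLUMNS, MODEL_COLUMNS

ParamKey = Tuple[str, str, str]

__all__ = [
    "ParamKey",
    "SemModelSpec",
    "build_structural_spec",
    "build_measurement_spec",
    "constrain_variable_paths",
    "model_df",
]


class IdentificationError(ValueError):
    """The specification cannot be identified as posed."""


@dataclass(frozen=True)
class SemModelSpec:
    observed: Tuple[str, ...]
    latents: Tuple[Tuple[str, Tuple[str, ...]], ...] = ()
    paths: Tuple[Tuple[str, str], ...] = ()
    covariances: Tuple[Tuple[str, str], ...] = ()
    correlated_residuals: Tuple[Tuple[str, str], ...] = ()
    fixed: Tuple[Tuple[ParamKey, float], ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def create(
        observed: Sequence[str],
        latents: Optional[Mapping[str, Sequence[str]]] = None,
        paths: Sequence[Tuple[str, str]] = (),
        covariances: Sequence[Tuple[str, str]] = (),
        correlated_residuals: Sequence[Tuple[str, str]] = (),
        fixed: Optional[Mapping[ParamKey, float]] = None,
    ) -> "SemModelSpec":
        lat = tuple(
            (name, tuple(inds)) for name, inds in (latents or {}).items()
        )
        spec = SemModelSpec(
            observed=tuple(observed),
            latents=lat,
            paths=tuple((str(a), str(b)) for a, b in paths),
            covariances=tuple((str(a), str(b)) for a, b in covariances),
            correlated_residuals=tuple(
                (str(a), str(b)) for a, b in correlated_residuals
            ),
            fixed=tuple(sorted((fixed or {}).items())),
        )
        spec.validate()
        return spec

    # -- basic structure -------------------------------------------------------

    @property
    def latent_names(self) -> Tuple[str, ...]:
        return tuple(name for name, _ in self.latents)

    @property
    def variables(self) -> Tuple[str, ...]:
        """Observed variables followed by latents."""
        return self.observed + self.latent_names

    @property
    def fixed_map(self) -> dict:
        return dict(self.fixed)

    def indicators_of(self, latent: str) -> Tuple[str, ...]:
        for name, inds in self.latents:
            if name == latent:
                return inds
        raise KeyError(latent)

    def endogenous(self) -> set:
        """Variables receiving a directed edge (path or loading)."""
        targets = {dst for _, dst in self.paths}
        targets |= {k[2] for k, _ in self.fixed if k[0] == "path"}
        for _, inds in self.latents:
            targets |= set(inds)
        return targets

    # -- parameter table --------------------------------------------------------

    def parameters(self) -> Tuple[Tuple[ParamKey, Optional[float]], ...]:
        """Ordered (key, fixed_value_or_None) pairs; None means free."""
        fixed = self.fixed_map
        out: list[tuple[ParamKey, Optional[float]]] = []
        for lat, inds in self.latents:
            for ind in inds:
                key = ("loading", lat, ind)
                out.append((key, fixed.get(key)))
        for src, dst in self.paths:
            key = ("path", src, dst)
            out.append((key, fixed.get(key)))
        for k, v in self.fixed:
            if k[0] == "path" and (k[1], k[2]) not in self.paths:
                out.append((k, v))
        for v_name in self.variables:
            key = ("var", v_name, v_name)
            out.append((key, fixed.get(key)))
        for a, b in self.covariances + self.correlated_residuals:
            key = ("cov", a, b)
            out.append((key, fixed.get(key)))
        return tuple(out)

    def free_keys(self) -> Tuple[ParamKey, ...]:
        return tuple(k for k, v in self.parameters() if v is None)

    @property
    def n_free(self) -> int:
        return len(self.free_keys())

    # -- validation -------------------------------------------------------------

    def validate(self) -> None:
        names = self.variables
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        for src, dst in self.paths:
            for v in (src, dst):
                if v not in names:
                    raise ValueError(f"path references unknown variable {v!r}")
        for a, b in self.covariances + self.correlated_residuals:
            for v in (a, b):
                if v not in names:
                    raise ValueError(f"covariance references unknown variable {v!r}")
        seen = set()
        for k, _ in self.parameters():
            canon = (k[0], k[2], k[1]) if k[0] == "cov" else k
            if canon in seen:
                raise ValueError(f"parameter {k} appears more than once")
            seen.add(canon)
        # acyclic structural graph
        adj: dict[str, list[str]] = {v: [] for v in names}
        for src, dst in self.paths:
            adj[src].append(dst)
        state: dict[str, int] = {}

        def dfs(v: str) -> None:
            state[v] = 1
            for w in adj[v]:
                if state.get(w) == 1:
                    raise ValueError(f"directed-path cycle through {w!r}")
                if state.get(w, 0) == 0:
                    dfs(w)
            state[v] = 2

        for v in names:
            if state.get(v, 0) == 0:
                dfs(v)
        # latent scale
        fixed = self.fixed_map
        for lat, inds in self.latents:
            if len(inds) < 2 and ("var", lat, lat) not in fixed:
                raise IdentificationError(
                    f"latent {lat!r} needs >= 2 indicators or a fixed variance"
                )

    def scale_is_set(self, latent: str) -> bool:
        fixed = self.fixed_map
        if ("var", latent, latent) in fixed:
            return True
        return any(
            ("loading", latent, ind) in fixed for ind in self.indicators_of(latent)
        )

    # -- serialisation ----------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "observed": list(self.observed),
            "latents": {name: list(inds) for name, inds in self.latents},
            "paths": [list(p) for p in self.paths],
            "covariances": [list(c) for c in self.covariances],
            "correlated_residuals": [list(c) for c in self.correlated_residuals],
            "fixed": [[list(k), v] for k, v in self.fixed],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @staticmethod
    def from_dict(d: Mapping) -> "SemModelSpec":
        return SemModelSpec.create(
            observed=d["observed"],
            latents=d.get("latents", {}),
            paths=[tuple(p) for p in d.get("paths", [])],
            covariances=[tuple(c) for c in d.get("covariances", [])],
            correlated_residuals=[
                tuple(c) for c in d.get("correlated_residuals", [])
            ],
            fixed={tuple(k): v for k, v in d.get("fixed", [])},
        )

    @staticmethod
    def from_file(path) -> "SemModelSpec":
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return SemModelSpec.from_dict(yaml.safe_load(text))
        return SemModelSpec.from_dict(json.loads(text))


# -- canonical model -----------------------------------------------------------

DEFAULT_CORRELATED_RESIDUALS = (
    ("gm_angular_gyrus", "gm_precuneus"),
    ("gm_superior_frontal_gyrus", "gm_frontal_pole"),
)

LATENT_INDICATORS = {
    "gm": GM_COLUMNS,
    "wm": ("slf_icvf", "slf_od"),
    "ef": ("rt", "pairs"),
}


def build_structural_spec(
    correlated_residuals: Sequence[Tuple[str, str]] = DEFAULT_CORRELATED_RESIDUALS,
    marker_identification: bool = True,
) -> SemModelSpec:
    """The full structural model linking age, cerebrovascular risk, WMH
    load and the frontoparietal network to executive function.

    Observed structural variables: standardised age, the CVR score and
    cube-root WMH load.  Latents: frontoparietal grey-matter volume
    (``gm``, six regional volumes), white-matter integrity of the
    superior longitudinal fasciculus (``wm``: ICVF and OD) and executive
    function (``ef``: negated reaction time and negated pairs errors).
    Directed paths: age and CVR to WMH; age, CVR and WMH to each of
    ``gm`` and ``wm``; ``gm`` and ``wm`` to ``ef``.  Age covaries with
    CVR.  No direct age/CVR/WMH -> ef paths: the network fully mediates,
    which is what makes each variable-constrained nested comparison lose
    exactly four free parameters.
    """
    fixed: dict[ParamKey, float] = {}
    if marker_identification:
        for lat, inds in LATENT_INDICATORS.items():
            fixed[("loading", lat, inds[0])] = 1.0
    return SemModelSpec.create(
        observed=MODEL_COLUMNS,
        latents=LATENT_INDICATORS,
        paths=(
            ("age", "wmh"),
            ("cvr", "wmh"),
            ("age", "gm"),
            ("cvr", "gm"),
            ("wmh", "gm"),
            ("age", "wm"),
            ("cvr", "wm"),
            ("wmh", "wm"),
            ("gm", "ef"),
            ("wm", "ef"),
        ),
        covariances=(("age", "cvr"),),
        correlated_residuals=correlated_residuals,
        fixed=fixed,
    )


def build_measurement_spec(
    correlated_residuals: Sequence[Tuple[str, str]] = DEFAULT_CORRELATED_RESIDUALS,
) -> SemModelSpec:
    """Measurement-only CFA: the three latents with free pairwise
    covariances and the default correlated residuals."""
    fixed: dict[ParamKey, float] = {
        ("loading", lat, inds[0]): 1.0 for lat, inds in LATENT_INDICATORS.items()
    }
    return SemModelSpec.create(
        observed=tuple(c for c in MODEL_COLUMNS if c not in ("age", "cvr", "wmh")),
        latents=LATENT_INDICATORS,
        paths=(),
        covariances=(("gm", "wm"), ("gm", "ef"), ("wm", "ef")),
        correlated_residuals=correlated_residuals,
        fixed=fixed,
    )


def constrain_variable_paths(spec: SemModelSpec, variable: str) -> SemModelSpec:
    """Fix every free directed path touching ``variable`` to zero.

    Loadings and covariances are untouched; the free-parameter count
    drops by exactly the number of such paths.
    """
    if variable not in spec.variables:
        raise KeyError(f"unknown variable {variable!r}")
    fixed = spec.fixed_map
    for src, dst in spec.paths:
        if variable in (src, dst) and ("path", src, dst) not in fixed:
            fixed[("path", src, dst)] = 0.0
    return replace(spec, fixed=tuple(sorted(fixed.items())))


def model_df(spec: SemModelSpec, p: Optional[int] = None) -> int:
    """Covariance-ML degrees of freedom: p(p+1)/2 minus free parameters."""
    p = len(spec.observed) if p is None else p
    df = p * (p + 1) // 2 - spec.n_free
    if df < 0:
        raise IdentificationError(
            f"negative degrees of freedom ({df}); model not identified"
        )
    return df
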