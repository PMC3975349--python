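"""Mode registry: the 13 built-in descriptor modes plus user plugins.

A :class:`ModeSpec` bundles everything the batch engine needs to run one
descriptor family: a parameter schema with defaults, the side inputs it
requires (property table, annotation map, PSSMs, distance matrices), a
dimensionality function, and the compute function itself.  User-defined
modes are plain Python modules exporting a ``MODE`` object with the same
contract, loaded with :func:`register_plugin`; a broken plugin raises
before registration and never corrupts the built-in registry.
"""

from __future__ import annotations

import importlib.util
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np

from . import data as _data
from .annotations import AnnotationMap
from .autocorr import FAMILIES, AutocorrParams, autocorr_vector
from .composition import aac, dipeptide, tripeptide
from .ctd import PropertyGrouping, ctd_vector
from .errors import ConfigurationError, PluginContractError
from .io import PropertyTable, ProteinRecord
from .pseaac_core import CLASSIC_PAIR, CLASSIC_TRIPLE, PseAACParams, type1_pseaac, type2_pseaac
from .pssm import PSSMatrix, normalize_pssm, psepssm
from .qso import DistanceMatrix, qso_mode_vector
from .vector import DescriptorVector

BUILTIN_MODE_NAMES = (
    "aac", "dpc", "tpc", "pseaac1", "pseaac2", "go", "fdom",
    "psepssm", "nmbroto", "moran", "geary", "ctd", "qso",
)


@dataclass
class Resources:
    """Side inputs shared by a batch run."""

    property_table: PropertyTable | None = None
    groupings: tuple[PropertyGrouping, ...] = ()
    distance_matrices: list[DistanceMatrix] = field(default_factory=list)
    annotation_maps: dict[str, AnnotationMap] = field(default_factory=dict)
    pssms: dict[str, PSSMatrix] = field(default_factory=dict)

    def require_table(self, mode: str) -> PropertyTable:
        if self.property_table is None or len(self.property_table) == 0:
            raise ConfigurationError(f"mode {mode!r} requires a property table")
        return self.property_table

    def require_map(self, mode: str) -> AnnotationMap:
        amap = self.annotation_maps.get(mode)
        if amap is None:
            raise ConfigurationError(
                f"mode {mode!r} requires an annotation map (--annotations)"
            )
        return amap

    def require_pssm(self, mode: str, rec_id: str) -> PSSMatrix:
        m = self.pssms.get(rec_id)
        if m is None:
            raise ConfigurationError(
                f"mode {mode!r}: no PSSM registered for accession {rec_id!r}"
            )
        return m


def default_resources() -> Resources:
    """Bundled defaults: classic 3-property table, 7 CTD groupings, both
    coupling matrices; no annotations or PSSMs."""
    return Resources(
        property_table=_data.classic_property_table(),
        groupings=_data.standard_groupings(),
        distance_matrices=_data.default_distance_matrices(),
    )


@dataclass(frozen=True)
class ModeSpec:
    """Contract for one descriptor mode (built-in or plugin)."""

    name: str
    description: str
    params: dict[str, tuple[type, Any]]  # name -> (type, default)
    requires: tuple[str, ...]  # subset of {"properties","annotations","pssms","matrices"}
    dim: Callable[[dict, Resources], int]
    compute: Callable[[ProteinRecord, dict, Resources], DescriptorVector]

    def defaults(self) -> dict[str, Any]:
        return {k: d for k, (_, d) in self.params.items()}

    def resolve_params(self, overrides: dict[str, Any] | None) -> dict[str, Any]:
        """Merge overrides into defaults, coercing strings per schema."""
        merged = self.defaults()
        for key, value in (overrides or {}).items():
            if key not in self.params:
                raise ConfigurationError(
                    f"mode {self.name!r}: unknown parameter {key!r} "
                    f"(accepts {sorted(self.params)})"
                )
            typ, _ = self.params[key]
            if isinstance(value, str) and typ is not str:
                if typ is tuple:
                    value = tuple(v for v in value.split(",") if v)
                else:
                    value = typ(value)
            merged[key] = value
        return merged


class Registry:
    """Name -> ModeSpec map with uniqueness enforcement."""

    def __init__(self):
        self._modes: dict[str, ModeSpec] = {}

    def register(self, spec: ModeSpec) -> None:
        if spec.name in self._modes:
            raise ConfigurationError(f"mode {spec.name!r} already registered")
        self._modes[spec.name] = spec

    def get(self, name: str) -> ModeSpec:
        try:
            return self._modes[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown mode {name!r}; available: {', '.join(self._modes)}"
            ) from None

    def names(self) -> list[str]:
        return list(self._modes)

    def __len__(self) -> int:
        return len(self._modes)

    def __contains__(self, name: str) -> bool:
        return name in self._modes

    def compute_checked(
        self,
        name: str,
        rec: ProteinRecord,
        params: dict | None,
        resources: Resources,
    ) -> DescriptorVector:
        """Run a mode and enforce the dim(params) == len(vector) contract."""
        spec = self.get(name)
        merged = spec.resolve_params(params)
        vec = spec.compute(rec, merged, resources)
        expected = spec.dim(merged, resources)
        if len(vec) != expected:
            raise PluginContractError(
                f"mode {name!r} declared dim {expected} but emitted "
                f"{len(vec)} values for record {rec.id!r}"
            )
        return vec


# ---------------------------------------------------------------------------
# built-in modes
# ---------------------------------------------------------------------------


def _autocorr_props(params: dict, res: Resources, mode: str) -> tuple[str, ...]:
    props = params.get("properties") or ()
    if props:
        return tuple(props)
    if res.property_table is None:
        return ()  # dim() degenerates to 0; compute() will demand a table
    return tuple(res.property_table.ids())  # default: every table entry


def _make_autocorr_spec(family: str) -> ModeSpec:
    label = {
        "nmbroto": "normalized Moreau-Broto autocorrelation",
        "moran": "Moran autocorrelation",
        "geary": "Geary autocorrelation",
    }[family]

    def dim(params: dict, res: Resources) -> int:
        return len(_autocorr_props(params, res, family)) * params["max_lag"]

    def compute(rec: ProteinRecord, params: dict, res: Resources):
        ap = AutocorrParams(
            max_lag=params["max_lag"],
            properties=_autocorr_props(params, res, family),
        )
        return autocorr_vector(rec, ap, family, res.require_table(family))

    return ModeSpec(
        name=family,
        description=f"{label} (per property, lags 1..D)",
        params={"max_lag": (int, 30), "properties": (tuple, ())},
        requires=("properties",),
        dim=dim,
        compute=compute,
    )


def _builtin_specs() -> list[ModeSpec]:
    specs: list[ModeSpec] = [
        ModeSpec(
            "aac", "amino acid composition (20 frequencies)",
            params={}, requires=(),
            dim=lambda p, r: 20,
            compute=lambda rec, p, r: aac(rec),
        ),
        ModeSpec(
            "dpc", "di-peptide composition (400 frequencies)",
            params={}, requires=(),
            dim=lambda p, r: 400,
            compute=lambda rec, p, r: dipeptide(rec),
        ),
        ModeSpec(
            "tpc", "tri-peptide composition (8000 frequencies)",
            params={}, requires=(),
            dim=lambda p, r: 8000,
            compute=lambda rec, p, r: tripeptide(rec),
        ),
        ModeSpec(
            "pseaac1",
            "Type I pseudo-amino-acid composition (20 + lambda)",
            params={
                "lam": (int, 30), "w": (float, 0.05),
                "properties": (tuple, CLASSIC_TRIPLE),
            },
            requires=("properties",),
            dim=lambda p, r: 20 + p["lam"],
            compute=lambda rec, p, r: type1_pseaac(
                rec,
                PseAACParams(lam=p["lam"], w=p["w"], properties=p["properties"]),
                r.require_table("pseaac1"),
            ),
        ),
        ModeSpec(
            "pseaac2",
            "Type II (amphiphilic) pseudo-amino-acid composition (20 + 2*lambda)",
            params={
                "lam": (int, 30), "w": (float, 0.05),
                "properties": (tuple, CLASSIC_PAIR),
            },
            requires=("properties",),
            dim=lambda p, r: 20 + 2 * p["lam"],
            compute=lambda rec, p, r: type2_pseaac(
                rec,
                PseAACParams(lam=p["lam"], w=p["w"], properties=p["properties"]),
                r.require_table("pseaac2"),
            ),
        ),
        ModeSpec(
            "go", "gene ontology binary presence vector",
            params={}, requires=("annotations",),
            dim=lambda p, r: r.require_map("go").n_terms,
            compute=lambda rec, p, r: r.require_map("go").binary_vector(rec.id, "go"),
        ),
        ModeSpec(
            "fdom", "functional domain binary presence vector",
            params={}, requires=("annotations",),
            dim=lambda p, r: r.require_map("fdom").n_terms,
            compute=lambda rec, p, r: r.require_map("fdom").binary_vector(rec.id, "fdom"),
        ),
        ModeSpec(
            "psepssm",
            "sequential evolution mode: pseudo-PSSM (20 + 20*xi)",
            params={"xi": (int, 10)},
            requires=("pssms",),
            dim=lambda p, r: 20 + 20 * p["xi"],
            compute=lambda rec, p, r: psepssm(
                normalize_pssm(r.require_pssm("psepssm", rec.id)), xi=p["xi"]
            ),
        ),
        _make_autocorr_spec("nmbroto"),
        _make_autocorr_spec("moran"),
        _make_autocorr_spec("geary"),
        ModeSpec(
            "ctd",
            "composition-transition-distribution (21 per grouping)",
            params={}, requires=(),
            dim=lambda p, r: 21 * len(r.groupings),
            compute=lambda rec, p, r: ctd_vector(rec, list(r.groupings)),
        ),
        ModeSpec(
            "qso",
            "quasi-sequence-order (20 + D per distance matrix)",
            params={"max_lag": (int, 30), "w": (float, 0.1)},
            requires=("matrices",),
            dim=lambda p, r: len(r.distance_matrices) * (20 + p["max_lag"]),
            compute=lambda rec, p, r: qso_mode_vector(
                rec, r.distance_matrices, p["max_lag"], p["w"]
            ),
        ),
    ]
    return specs


def register_builtin_modes() -> Registry:
    """Registry holding exactly the 13 built-in modes."""
    registry = Registry()
    for spec in _builtin_specs():
        registry.register(spec)
    assert registry.names() == list(BUILTIN_MODE_NAMES)
    return registry


def register_plugin(registry: Registry, module_path) -> ModeSpec:
    """Load a plugin module exporting ``MODE`` (a ModeSpec) and register it.

    The contract is validated before the registry is touched, so a broken
    plugin cannot leave the registry half-updated.
    """
    path = Path(module_path)
    if not path.exists():
        raise PluginContractError(f"plugin file not found: {path}")
    spec_loader = importlib.util.spec_from_file_location(
        f"pseaac_plugin_{path.stem}", path
    )
    if spec_loader is None or spec_loader.loader is None:
        raise PluginContractError(f"cannot import plugin {path}")
    module = importlib.util.module_from_spec(spec_loader)
    try:
        spec_loader.loader.exec_module(module)
    except Exception as exc:
        raise PluginContractError(f"plugin {path} failed to import: {exc}") from exc
    mode = getattr(module, "MODE", None)
    if mode is None:
        raise PluginContractError(f"plugin {path} does not export MODE")
    missing = [
        attr for attr in ("name", "description", "params", "requires", "dim", "compute")
        if not hasattr(mode, attr)
    ]
    if missing:
        raise PluginContractError(
            f"plugin {path}: MODE is missing contract members {missing}"
        )
    if not isinstance(mode, ModeSpec):
        mode = ModeSpec(
            name=mode.name, description=mode.description,
            params=dict(mode.params), requires=tuple(mode.requires),
            dim=mode.dim, compute=mode.compute,
        )
    registry.register(mode)  # duplicate names rejected here
    return mode


def enumerate_descriptor_space(
    property_count: int,
    params_by_mode: dict[str, dict] | None = None,
    go_terms: int = 0,
    fdom_terms: int = 0,
) -> int:
    """Total output dimensionality across the 13 built-in modes.

    Dimensions are summed at default parameters (lambda=30, D=30, xi=10,
    7 CTD groupings, 2 distance matrices) for a property table with
    ``property_count`` entries; the binary annotation modes contribute
    their universe sizes (0 when no map is loaded).  With a full
    544-property table the autocorrelation families alone contribute
    3 x 544 x 30 = 48,960 features.
    """
    registry = register_builtin_modes()
    table = PropertyTable()
    for i in range(property_count):
        # dim() only counts entries; constant placeholder values suffice
        table.add(f"P{i + 1:04d}", np.arange(20, dtype=float))
    dummy_universe = lambda n: AnnotationMap(  # noqa: E731
        universe=tuple(f"T{j:06d}" for j in range(n)),
        assignments={},
    )
    res = Resources(
        property_table=table,
        groupings=_data.standard_groupings(),
        distance_matrices=_data.default_distance_matrices(),
        annotation_maps={
            "go": dummy_universe(go_terms),
            "fdom": dummy_universe(fdom_terms),
        },
    )
    total = 0
    for name in registry.names():
        spec = registry.get(name)
        overrides = (params_by_mode or {}).get(name)
        total += spec.dim(spec.resolve_params(overrides), res)
    return total
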