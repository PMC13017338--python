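"""Editable coefficient registry for the six prediction equations.

The registry is a YAML mapping of equation id to an :class:`EquationSpec`.
A default registry is shipped with the package; a user file may override
individual equations or supply a complete replacement. Keeping the
coefficients in data rather than code isolates coefficient provenance:
they can be corrected against the source publications without touching
the evaluators.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "CANONICAL_IDS",
    "EquationSpec",
    "RegistryError",
    "load_equation_registry",
    "default_registry",
    "write_registry",
    "registry_hash",
]

#: The six equation ids the comparison pipeline expects, in report order.
CANONICAL_IDS = ("friend", "wasserman", "hansen", "bruce", "jones", "neder")

_FORMS = ("per_kg_linear", "weight_linear", "ideal_weight_branched", "absolute_linear")
_WEIGHT_UNITS = ("kg", "lb")
_HEIGHT_UNITS = ("cm", "in")
_MODES = ("treadmill", "cycle")


class RegistryError(ValueError):
    """Malformed, incomplete, or inconsistent equation registry."""


@dataclass(frozen=True)
class EquationSpec:
    """One prediction equation: functional form plus named coefficients.

    ``coefficients`` is either a flat name→number map (shared across sexes,
    with explicit ``sex_code``/``mode_code`` terms, as for FRIEND) or a
    ``{"male": {...}, "female": {...}}`` branch map.
    """

    id: str
    form: str
    native_modes: tuple[str, ...]
    coefficients: dict
    weight_units: str = "kg"
    height_units: str = "cm"
    scale: float = 1.0
    treadmill_factor: float | None = None
    source_age_range: tuple[float, float] | None = None
    name: str = ""
    provenance: str = "published"

    @property
    def sex_branched(self) -> bool:
        return set(self.coefficients) <= {"male", "female"} and bool(self.coefficients)

    def coeffs_for(self, sex: str) -> dict:
        """The coefficient map applying to ``sex``."""
        if self.sex_branched:
            try:
                return self.coefficients[sex]
            except KeyError:
                raise RegistryError(
                    f"equation {self.id!r} has no coefficient branch for sex {sex!r}"
                ) from None
        return self.coefficients


class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys (duplicate ids)."""


def _strict_mapping(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise RegistryError(f"duplicate registry key {key!r}")
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_mapping
)


def _validate_numbers(eq_id: str, coeffs: dict) -> None:
    for key, value in coeffs.items():
        if isinstance(value, dict):
            _validate_numbers(eq_id, value)
        elif not isinstance(value, (int, float)) or isinstance(value, bool):
            raise RegistryError(
                f"equation {eq_id!r}: coefficient {key!r} is not a number ({value!r})"
            )


def _parse_spec(eq_id: str, block: dict) -> EquationSpec:
    if not isinstance(block, dict):
        raise RegistryError(f"equation {eq_id!r}: block must be a mapping")
    form = block.get("form")
    if form not in _FORMS:
        raise RegistryError(f"equation {eq_id!r}: unknown form {form!r}")
    weight_units = block.get("weight_units", "kg")
    if weight_units not in _WEIGHT_UNITS:
        raise RegistryError(
            f"equation {eq_id!r}: unknown weight units {weight_units!r}"
        )
    height_units = block.get("height_units", "cm")
    if height_units not in _HEIGHT_UNITS:
        raise RegistryError(
            f"equation {eq_id!r}: unknown height units {height_units!r}"
        )
    modes = tuple(block.get("native_modes", ()))
    if not modes or any(m not in _MODES for m in modes) or len(set(modes)) != len(modes):
        raise RegistryError(
            f"equation {eq_id!r}: native_modes must be a non-empty subset of {_MODES}"
        )
    coefficients = block.get("coefficients")
    if not isinstance(coefficients, dict) or not coefficients:
        raise RegistryError(f"equation {eq_id!r}: missing coefficients")
    _validate_numbers(eq_id, coefficients)
    age_range = block.get("source_age_range")
    if age_range is not None:
        age_range = tuple(float(a) for a in age_range)
        if len(age_range) != 2 or age_range[0] >= age_range[1]:
            raise RegistryError(f"equation {eq_id!r}: bad source_age_range")
    return EquationSpec(
        id=eq_id,
        form=form,
        native_modes=modes,
        coefficients=coefficients,
        weight_units=weight_units,
        height_units=height_units,
        scale=float(block.get("scale", 1.0)),
        treadmill_factor=(
            float(block["treadmill_factor"]) if "treadmill_factor" in block else None
        ),
        source_age_range=age_range,
        name=str(block.get("name", eq_id)),
        provenance=str(block.get("provenance", "published")),
    )


def _parse_registry(text: str, *, allow_partial: bool) -> dict[str, EquationSpec]:
    try:
        raw = yaml.load(text, Loader=_StrictLoader)
    except yaml.YAMLError as exc:
        raise RegistryError(f"registry file does not parse as YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise RegistryError("registry file must be a mapping of equation ids")
    registry = {eq_id: _parse_spec(eq_id, block) for eq_id, block in raw.items()}
    missing = [i for i in CANONICAL_IDS if i not in registry]
    if missing and not allow_partial:
        raise RegistryError(f"registry is missing equations: {', '.join(missing)}")
    return registry


def _default_text() -> str:
    return (
        resources.files("vo2compare.data").joinpath("equations.yaml").read_text("utf-8")
    )


def default_registry() -> dict[str, EquationSpec]:
    """The built-in six-equation registry."""
    return _parse_registry(_default_text(), allow_partial=False)


def load_equation_registry(
    path: str | Path | None = None, *, allow_partial: bool = False
) -> dict[str, EquationSpec]:
    """Load the registry from ``path``, merged over the built-in default.

    A user file may redefine any subset of equations; the remaining
    equations keep their default coefficients. With ``allow_partial`` a
    registry lacking some canonical ids is accepted (the pipeline itself
    still requires all six).
    """
    registry = _parse_registry(_default_text(), allow_partial=False)
    if path is not None:
        override = _parse_registry(
            Path(path).read_text("utf-8"), allow_partial=True
        )
        registry.update(override)
    if not allow_partial:
        missing = [i for i in CANONICAL_IDS if i not in registry]
        if missing:
            raise RegistryError(f"registry is missing equations: {', '.join(missing)}")
    return registry


def _spec_to_block(spec: EquationSpec) -> dict:
    block: dict = {
        "name": spec.name,
        "form": spec.form,
        "native_modes": list(spec.native_modes),
        "weight_units": spec.weight_units,
        "height_units": spec.height_units,
        "coefficients": spec.coefficients,
    }
    if spec.scale != 1.0:
        block["scale"] = spec.scale
    if spec.treadmill_factor is not None:
        block["treadmill_factor"] = spec.treadmill_factor
    if spec.source_age_range is not None:
        block["source_age_range"] = list(spec.source_age_range)
    if spec.provenance != "published":
        block["provenance"] = spec.provenance
    return block


def write_registry(registry: dict[str, EquationSpec], path: str | Path) -> None:
    """Serialize a registry back to YAML (round-trips through the loader)."""
    blocks = {eq_id: _spec_to_block(spec) for eq_id, spec in registry.items()}
    Path(path).write_text(
        yaml.safe_dump(blocks, sort_keys=False, allow_unicode=True), "utf-8"
    )


def registry_hash(registry: dict[str, EquationSpec]) -> str:
    """Short stable digest of the coefficient set, echoed in reports."""
    blocks = {eq_id: _spec_to_block(spec) for eq_id, spec in sorted(registry.items())}
    payload = yaml.safe_dump(blocks, sort_keys=True).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()[:12]
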