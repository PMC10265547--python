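"""Declarative bundle-dissection registry.

A registry is an ordered collection of bundle definitions, each describing how
to extract one named white-matter bundle from a whole-brain tractogram:
volumes of interest (VOIs) the streamlines must pass through (``includes``,
logical AND), must avoid (``excludes``, logical OR — any hit rejects), and
optionally must terminate in (``endpoint_includes``), plus filter parameters
and a failure threshold.

The built-in default registry encodes a 68-bundle dissection protocol:
15 bilateral association families, 8 commissural bundles (anterior commissure
plus the corpus callosum in 7 segments), 12 bilateral projection families and
3 bilateral cerebellar families. Label-based VOIs in the default registry use
a symbolic region vocabulary (see :data:`REGION_VOCABULARY`) that resolves
against the bundled phantom parcellation; real atlas label IDs can be
substituted via ``label_ids`` in a user-supplied registry file.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field

import yaml

__all__ = [
    "VOISpec",
    "BundleDefinition",
    "BundleRegistry",
    "SchemaError",
    "load_registry",
    "save_registry",
    "default_registry",
    "census",
    "REGION_VOCABULARY",
]

GROUPS = ("association", "commissural", "projection", "cerebellar")
HEMISPHERES = ("left", "right", "midline")
VOI_KINDS = ("labels", "box", "midsagittal", "dilated")


class SchemaError(ValueError):
    """A registry config violates the schema; the message names the entry."""


@dataclass(frozen=True)
class VOISpec:
    """One volume-of-interest specification.

    kind="labels"      -> union of parcellation labels (``label_names`` are
                          symbolic and resolved via the parcellation's label
                          table; ``label_ids`` are raw integer labels)
    kind="box"         -> axis-aligned world-mm box given by two corners
    kind="midsagittal" -> slab of given thickness around the grid's mid-plane
    kind="dilated"     -> another VOISpec dilated N times (6-connected)
    """

    kind: str
    label_names: tuple[str, ...] = ()
    label_ids: tuple[int, ...] = ()
    corners_mm: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None
    thickness_mm: float | None = None
    base: "VOISpec | None" = None
    iterations: int | None = None

    def __post_init__(self):
        if self.kind not in VOI_KINDS:
            raise SchemaError(f"unknown VOI kind {self.kind!r}")
        if self.kind == "labels":
            if not (self.label_names or self.label_ids):
                raise SchemaError("labels VOI needs non-empty label_names or label_ids")
        elif self.kind == "box":
            if self.corners_mm is None or len(self.corners_mm) != 2:
                raise SchemaError("box VOI needs corners_mm = two world points")
        elif self.kind == "midsagittal":
            if self.thickness_mm is None or self.thickness_mm <= 0:
                raise SchemaError("midsagittal VOI needs thickness_mm > 0")
        elif self.kind == "dilated":
            if self.base is None or self.iterations is None or self.iterations < 0:
                raise SchemaError("dilated VOI needs base spec and iterations >= 0")

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        if self.kind == "labels":
            if self.label_names:
                d["label_names"] = list(self.label_names)
            if self.label_ids:
                d["label_ids"] = [int(i) for i in self.label_ids]
        elif self.kind == "box":
            d["corners_mm"] = [list(c) for c in self.corners_mm]
        elif self.kind == "midsagittal":
            d["thickness_mm"] = float(self.thickness_mm)
        elif self.kind == "dilated":
            d["base"] = self.base.to_dict()
            d["iterations"] = int(self.iterations)
        return d

    @classmethod
    def from_dict(cls, d: dict, where: str = "") -> "VOISpec":
        if not isinstance(d, dict) or "kind" not in d:
            raise SchemaError(f"{where}: VOI spec must be a mapping with a 'kind'")
        kind = d["kind"]
        known = {"kind", "label_names", "label_ids", "corners_mm", "thickness_mm", "base", "iterations"}
        extra = set(d) - known
        if extra:
            raise SchemaError(f"{where}: unknown VOI fields {sorted(extra)}")
        kwargs: dict = {"kind": kind}
        if kind == "labels":
            kwargs["label_names"] = tuple(d.get("label_names", ()))
            kwargs["label_ids"] = tuple(int(i) for i in d.get("label_ids", ()))
        elif kind == "box":
            corners = d.get("corners_mm")
            if corners is None:
                raise SchemaError(f"{where}: box VOI missing corners_mm")
            kwargs["corners_mm"] = tuple(tuple(float(x) for x in c) for c in corners)
        elif kind == "midsagittal":
            kwargs["thickness_mm"] = float(d.get("thickness_mm", 0) or 0)
        elif kind == "dilated":
            kwargs["base"] = cls.from_dict(d.get("base", {}), where=f"{where}.base")
            kwargs["iterations"] = int(d.get("iterations", -1))
        else:
            raise SchemaError(f"{where}: unknown VOI kind {kind!r}")
        return cls(**kwargs)


def _labels(*names: str) -> VOISpec:
    return VOISpec(kind="labels", label_names=tuple(names))


def _midsag(thickness_mm: float = 3.0) -> VOISpec:
    return VOISpec(kind="midsagittal", thickness_mm=thickness_mm)


@dataclass(frozen=True)
class BundleDefinition:
    name: str
    group: str
    hemisphere: str
    includes: tuple[VOISpec, ...]
    excludes: tuple[VOISpec, ...] = ()
    endpoint_includes: tuple[VOISpec, ...] = ()
    min_streamlines: int = 10
    length_bounds_mm: tuple[float, float] | None = None
    outlier_z: float | None = None

    def __post_init__(self):
        if not self.name:
            raise SchemaError("bundle definition needs a name")
        if self.group not in GROUPS:
            raise SchemaError(f"bundle {self.name!r}: unknown group {self.group!r}")
        if self.hemisphere not in HEMISPHERES:
            raise SchemaError(f"bundle {self.name!r}: unknown hemisphere {self.hemisphere!r}")
        if self.hemisphere == "midline" and self.group != "commissural":
            raise SchemaError(f"bundle {self.name!r}: hemisphere=midline only for commissural bundles")
        if not self.includes:
            raise SchemaError(f"bundle {self.name!r}: includes must be non-empty")
        if self.min_streamlines < 1:
            raise SchemaError(f"bundle {self.name!r}: min_streamlines must be >= 1")
        if self.length_bounds_mm is not None:
            lo, hi = self.length_bounds_mm
            if not (0 <= lo < hi):
                raise SchemaError(f"bundle {self.name!r}: bad length_bounds_mm {self.length_bounds_mm}")

    @property
    def family(self) -> str:
        """Bundle family name with any hemisphere suffix stripped."""
        for suffix in ("_left", "_right"):
            if self.name.endswith(suffix):
                return self.name[: -len(suffix)]
        return self.name

    def to_dict(self) -> dict:
        d: dict = {
            "name": self.name,
            "group": self.group,
            "hemisphere": self.hemisphere,
            "includes": [v.to_dict() for v in self.includes],
        }
        if self.excludes:
            d["excludes"] = [v.to_dict() for v in self.excludes]
        if self.endpoint_includes:
            d["endpoint_includes"] = [v.to_dict() for v in self.endpoint_includes]
        if self.min_streamlines != 10:
            d["min_streamlines"] = self.min_streamlines
        if self.length_bounds_mm is not None:
            d["length_bounds_mm"] = list(self.length_bounds_mm)
        if self.outlier_z is not None:
            d["outlier_z"] = self.outlier_z
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BundleDefinition":
        name = d.get("name", "<unnamed>")
        known = {"name", "group", "hemisphere", "includes", "excludes",
                 "endpoint_includes", "min_streamlines", "length_bounds_mm", "outlier_z"}
        extra = set(d) - known
        if extra:
            raise SchemaError(f"bundle {name!r}: unknown fields {sorted(extra)}")
        includes = d.get("includes") or []
        if not includes:
            raise SchemaError(f"bundle {name!r}: includes must be non-empty")
        return cls(
            name=d.get("name", ""),
            group=d.get("group", ""),
            hemisphere=d.get("hemisphere", ""),
            includes=tuple(VOISpec.from_dict(v, where=f"bundle {name!r} include") for v in includes),
            excludes=tuple(VOISpec.from_dict(v, where=f"bundle {name!r} exclude") for v in d.get("excludes", [])),
            endpoint_includes=tuple(
                VOISpec.from_dict(v, where=f"bundle {name!r} endpoint") for v in d.get("endpoint_includes", [])
            ),
            min_streamlines=int(d.get("min_streamlines", 10)),
            length_bounds_mm=tuple(d["length_bounds_mm"]) if d.get("length_bounds_mm") else None,
            outlier_z=float(d["outlier_z"]) if d.get("outlier_z") is not None else None,
        )


@dataclass
class BundleRegistry:
    definitions: list[BundleDefinition]
    version: str = "1.0"

    def __post_init__(self):
        seen = set()
        for b in self.definitions:
            if b.name in seen:
                raise SchemaError(f"duplicate bundle name {b.name!r}")
            seen.add(b.name)

    def __len__(self) -> int:
        return len(self.definitions)

    def __iter__(self):
        return iter(self.definitions)

    def __getitem__(self, name: str) -> BundleDefinition:
        for b in self.definitions:
            if b.name == name:
                return b
        raise KeyError(name)

    def filter(self, group: str | None = None, hemisphere: str | None = None) -> "BundleRegistry":
        defs = [
            b
            for b in self.definitions
            if (group is None or b.group == group) and (hemisphere is None or b.hemisphere == hemisphere)
        ]
        return BundleRegistry(defs, version=self.version)

    def to_dict(self) -> dict:
        return {"version": self.version, "bundles": [b.to_dict() for b in self.definitions]}


def census(registry: BundleRegistry) -> dict:
    """Group census: families counted once per hemisphere pair."""
    fams: dict[str, set[str]] = {g: set() for g in GROUPS}
    for b in registry:
        fams[b.group].add(b.family)
    return {
        "association_families": len(fams["association"]),
        "commissural": len([b for b in registry if b.group == "commissural"]),
        "projection_families": len(fams["projection"]),
        "cerebellar_families": len(fams["cerebellar"]),
        "total": len(registry),
    }


def save_registry(registry: BundleRegistry, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(registry.to_dict(), fh, sort_keys=False, allow_unicode=True)


def load_registry(config_source=None) -> BundleRegistry:
    """Load a registry from a YAML path / stream / mapping.

    With no argument, returns the built-in default 68-bundle registry.
    """
    if config_source is None:
        return default_registry()
    if isinstance(config_source, dict):
        doc = config_source
    elif hasattr(config_source, "read"):
        doc = yaml.safe_load(config_source)
    else:
        with open(config_source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "bundles" not in doc:
        raise SchemaError("registry config must be a mapping with a 'bundles' list")
    defs = [BundleDefinition.from_dict(b) for b in doc["bundles"]]
    return BundleRegistry(defs, version=str(doc.get("version", "1.0")))


def dumps_registry(registry: BundleRegistry) -> str:
    buf = _stdio.StringIO()
    yaml.safe_dump(registry.to_dict(), buf, sort_keys=False, allow_unicode=True)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Default 68-bundle protocol
# ---------------------------------------------------------------------------

#: Symbolic region vocabulary for label VOIs. Hemispheric regions carry an
#: ``_l`` / ``_r`` suffix; midline regions none. The phantom parcellation
#: binds every one of these names to an integer label.
_HEMI_REGIONS = (
    "prefrontal", "frontal", "premotor", "sma", "motor", "sensory",
    "parietal", "occipital", "temporal", "temporal_pole",
    "cingulate_ant", "cingulate_post", "hippocampus", "thalamus", "lgn",
    "red_nucleus", "dentate", "cerebellum", "pons", "medulla",
)
_MIDLINE_REGIONS = ("optic_chiasm",)

REGION_VOCABULARY: tuple[str, ...] = tuple(
    f"{r}_{s}" for r in _HEMI_REGIONS for s in ("l", "r")
) + _MIDLINE_REGIONS

# family -> list of include VOIs; each VOI a list of region stems
# (stems are suffixed per hemisphere; "~stem" = contralateral; "=name" = literal)
_ASSOCIATION = {
    "AF": [["premotor"], ["temporal"]],
    "CCing": [["cingulate_ant"], ["cingulate_post"]],
    "TCing": [["cingulate_post"], ["temporal"]],
    "FX": [["hippocampus"], ["thalamus"]],
    "FAT": [["sma"], ["frontal"]],
    "IFOF": [["prefrontal"], ["occipital"]],
    "ILF": [["temporal_pole"], ["occipital"]],
    "MdLF": [["temporal"], ["parietal"]],
    "SLF_whole": [["frontal", "premotor", "motor"], ["parietal"]],
    "SLF_I": [["sma"], ["parietal"]],
    "SLF_IId": [["premotor"], ["parietal"]],
    "SLF_IIv": [["frontal"], ["parietal"]],
    "SLF_III": [["motor"], ["parietal"]],
    "UF": [["prefrontal"], ["temporal_pole"]],
    "VOF": [["parietal"], ["occipital"]],
}

# commissural: stems joined across hemispheres, plus the midsagittal slab
_COMMISSURAL = {
    "AC": ["temporal_pole"],
    "CC_PreF": ["prefrontal"],
    "CC_PMC_SMA": ["premotor", "sma"],
    "CC_Motor": ["motor"],
    "CC_Sensory": ["sensory"],
    "CC_Parietal": ["parietal"],
    "CC_Occipital": ["occipital"],
    "CC_Temporal": ["temporal"],
}

_PROJECTION = {
    "ML": [["medulla"], ["thalamus"]],
    "OT": [["=optic_chiasm"], ["lgn"]],
    "OR": [["lgn"], ["occipital"]],
    # occipital-lobe variant of the optic radiation; also aliased as the
    # posterior thalamic radiation (not a separate registry entry)
    "OR_OL": [["lgn"], ["occipital"]],
    "PyT_all": [["motor", "premotor", "sma"], ["pons"], ["medulla"]],
    "CST": [["motor", "sensory"], ["pons"], ["medulla"]],
    "M1_CST": [["motor"], ["pons"], ["medulla"]],
    "PyT_PMC": [["premotor"], ["pons"], ["medulla"]],
    "PyT_SMA": [["sma"], ["pons"], ["medulla"]],
    "ATR": [["prefrontal"], ["thalamus"]],
    "STR": [["motor", "sensory"], ["thalamus"]],
    "PaTR": [["parietal"], ["thalamus"]],
}

_CEREBELLAR = {
    "DRTT": [["~dentate"], ["red_nucleus"], ["thalamus"]],
    "ICP": [["medulla"], ["cerebellum"]],
    "MCP": [["pons"], ["cerebellum"]],
}

#: families whose trajectory crosses the midline (no midsagittal exclude)
_CROSSING_FAMILIES = {"OT", "DRTT", "MCP"}

#: families with cortical termination semantics on their last include
_ENDPOINT_FAMILIES = {"OR", "OR_OL"}

#: alias for the posterior thalamic radiation, reconstructed as OR_OL
FAMILY_ALIASES = {"PoTR": "OR_OL"}


def _resolve_stem(stem: str, hemi_suffix: str, contra_suffix: str) -> str:
    if stem.startswith("="):
        return stem[1:]
    if stem.startswith("~"):
        return f"{stem[1:]}_{contra_suffix}"
    return f"{stem}_{hemi_suffix}"


def _bilateral_defs(table, group) -> list[BundleDefinition]:
    defs = []
    for family, voi_stems in table.items():
        for hemisphere, suf, contra in (("left", "l", "r"), ("right", "r", "l")):
            includes = tuple(
                _labels(*(_resolve_stem(s, suf, contra) for s in stems)) for stems in voi_stems
            )
            excludes = () if family in _CROSSING_FAMILIES else (_midsag(),)
            endpoints = (includes[-1],) if family in _ENDPOINT_FAMILIES else ()
            defs.append(
                BundleDefinition(
                    name=f"{family}_{hemisphere}",
                    group=group,
                    hemisphere=hemisphere,
                    includes=includes,
                    excludes=excludes,
                    endpoint_includes=endpoints,
                )
            )
    return defs


def default_registry() -> BundleRegistry:
    """The built-in 68-bundle dissection protocol."""
    defs: list[BundleDefinition] = []
    defs += _bilateral_defs(_ASSOCIATION, "association")
    for name, stems in _COMMISSURAL.items():
        includes = (
            _labels(*(f"{s}_l" for s in stems)),
            _labels(*(f"{s}_r" for s in stems)),
            _midsag(),
        )
        defs.append(
            BundleDefinition(
                name=name, group="commissural", hemisphere="midline", includes=includes
            )
        )
    defs += _bilateral_defs(_PROJECTION, "projection")
    defs += _bilateral_defs(_CEREBELLAR, "cerebellar")
    return BundleRegistry(defs, version="default-1.0")
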