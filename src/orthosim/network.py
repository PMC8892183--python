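"""Model topology, geometry and parameters: types, loading, validation.

A :class:`NetworkModel` bundles the 1D arterial tree (a rooted tree of
:class:`VesselSegment`), the lumped compartments of the microcirculation and
venous return (:class:`CompartmentSpec`), heart chambers, valves, regulation
parameters and blood properties. Configurations are YAML or JSON documents
(both parsed by the YAML loader) with a required ``model_version`` field;
geometry is in SI (m), lumped parameters in clinical units (mmHg, ml, s).

The longitudinal body axis z has its origin at the right atrium and is
positive toward the feet; hydrostatic generators between lumped compartments
are derived from the signed z positions of their pressure nodes, so
microvascular compartments of one region (which share the regional node
position and have zero anatomical height) never carry a hydrostatic column.
"""
from __future__ import annotations

import copy
import importlib.resources
import math
from dataclasses import dataclass, field

import yaml

from .arterial_1d import beta_from_wave_speed

SCHEMA_VERSION = 1

MICRO_KINDS = {"arteriole", "capillary", "venule"}
VENOUS_KINDS = {"vein", "vena_cava_superior", "vena_cava_inferior",
                "vena_cava_abdominal"}
COMPARTMENT_KINDS = MICRO_KINDS | VENOUS_KINDS | {
    "capillary", "pulmonary_artery", "pulmonary_vein"}
REGIONS = {"head", "arms", "upper_abdomen", "lower_abdomen", "legs",
           "thorax", "coronary"}
BODY_REGIONS = ("head", "arms", "upper_abdomen", "lower_abdomen", "legs")
EXTRAVASCULAR = {"ambient", "intrathoracic", "intracranial",
                 "intramyocardial"}


class ConfigurationError(ValueError):
    """Malformed configuration (missing/duplicate/unresolvable ids)."""


class ValidationError(ValueError):
    """A model invariant is violated; message names field and rule."""


@dataclass
class VesselSegment:
    """One tapered segment of the 1D arterial tree."""

    id: int
    name: str
    length: float             # m
    proximal_radius: float    # m
    distal_radius: float      # m
    wall_stiffness_beta: float  # Pa*m (elastic coefficient of the tube law)
    viscoelastic_coeff: float = 0.0  # Pa*s*m
    orientation_gamma: float = 0.0   # rad, w.r.t. frontal transverse axis
    longitudinal_projection: float = 0.0  # [-1, 1], feetward positive
    parent_id: int | None = None
    child_ids: list = field(default_factory=list)
    terminal_bed_id: str | None = None
    z_prox: float = 0.0       # m, signed position of the proximal end

    @property
    def z_dist(self) -> float:
        return self.z_prox + self.length * self.longitudinal_projection

    def area(self, s: float) -> float:
        r = self.proximal_radius + (self.distal_radius
                                    - self.proximal_radius) * s
        return math.pi * r * r


@dataclass
class CompartmentSpec:
    """One lumped compartment (RLC, or RLCR for arterioles)."""

    id: str
    kind: str
    region: str
    resistance: float         # mmHg s/ml (outflow branch)
    compliance: float         # ml/mmHg (C0 for the non-linear legs vein)
    inertance: float = 0.0    # mmHg s^2/ml
    volume_fraction: float = 0.0   # of the distributable blood pool
    unstressed_volume: float = 0.0  # ml; derived at initialization
    anatomical_height: float = 0.0  # m (0 for microvascular compartments)
    z_node: float = 0.0       # m, signed node position (feetward positive)
    extravascular_source: str = "ambient"
    downstream: str | None = None   # id of the next compartment / 'ra'
    valve: str | None = None        # venous valve on the outflow link
    terminal_of: int | None = None  # 1D vessel id (arterioles only)
    nonlinear_law: dict | None = None  # legs vein: {deltaV_max: ml}
    p_init: float = 10.0      # mmHg, initialization pressure

    @property
    def z_midpoint(self) -> float:
        return self.z_node


@dataclass
class NetworkModel:
    """Validated closed-loop model ready for compilation."""

    name: str
    model_version: int
    vessels: dict            # id -> VesselSegment
    compartments: dict       # id -> CompartmentSpec
    chambers: dict           # 'ra'/'rv'/'la'/'lv' -> params dict
    cardiac_valves: dict     # name -> params dict
    venous_valves: dict      # name -> params dict
    regulation: dict
    coronary: dict
    intrathoracic: dict
    icp: dict
    tilt_default: dict
    numerics: dict
    sites: dict              # name -> {vessel: id, s: fraction}
    blood_density: float
    blood_viscosity: float
    total_blood_volume: float
    raw: dict = field(default_factory=dict, repr=False)

    @property
    def root_vessel(self) -> VesselSegment:
        roots = [v for v in self.vessels.values() if v.parent_id is None]
        return roots[0]

    def terminal_vessels(self):
        return [v for v in self.vessels.values() if not v.child_ids]


# ----------------------------------------------------------------------------
# Loading
# ----------------------------------------------------------------------------

def _vessel_from_doc(doc: dict, rho: float) -> VesselSegment:
    d = dict(doc)
    if "beta" in d or "wall_stiffness_beta" in d:
        beta = d.get("wall_stiffness_beta", d.get("beta"))
    elif "c0" in d:
        A0d = math.pi * d["r_dist"] ** 2
        beta = beta_from_wave_speed(d["c0"], A0d, rho)
    else:
        raise ConfigurationError(
            f"vessel {d.get('id')}: neither beta nor c0 given")
    return VesselSegment(
        id=int(d["id"]), name=d.get("name", f"vessel_{d['id']}"),
        length=float(d["length"]),
        proximal_radius=float(d["r_prox"]),
        distal_radius=float(d["r_dist"]),
        wall_stiffness_beta=float(beta),
        viscoelastic_coeff=float(d.get("gamma_visc", 0.0)),
        orientation_gamma=float(d.get("gamma_deg", 0.0)) * math.pi / 180.0,
        longitudinal_projection=float(d.get("lambda", 0.0)),
        parent_id=d.get("parent"),
        terminal_bed_id=d.get("terminal_bed"),
        z_prox=float(d.get("z_prox", 0.0)),
    )


def load_network(source) -> NetworkModel:
    """Load and validate a model configuration.

    ``source`` may be a path to a YAML/JSON document, a YAML/JSON string, or
    an already-parsed mapping. Raises :class:`ConfigurationError` for
    unresolvable documents and :class:`ValidationError` for violated model
    invariants (naming the offending id/field).
    """
    if isinstance(source, dict):
        doc = copy.deepcopy(source)
    else:
        text = None
        try:
            import os
            if isinstance(source, (str, bytes)) and len(str(source)) < 4096 \
                    and os.path.exists(source):
                with open(source) as fh:
                    text = fh.read()
        except OSError:
            text = None
        if text is None:
            text = source
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse configuration: {exc}")
    if not isinstance(doc, dict):
        raise ConfigurationError("configuration root must be a mapping")
    if "model_version" not in doc:
        raise ConfigurationError("missing required field 'model_version'")

    blood = doc.get("blood", {})
    rho = float(blood.get("density", 1050.0))
    mu = float(blood.get("viscosity", 0.004))
    total = float(blood.get("total_volume", 5700.0))

    vessels = {}
    for vd in doc.get("vessels", []):
        v = _vessel_from_doc(vd, rho)
        if v.id in vessels:
            raise ConfigurationError(f"duplicate vessel id {v.id}")
        vessels[v.id] = v

    comps = {}
    for cd in doc.get("compartments", []):
        d = dict(cd)
        cid = d.pop("id")
        if cid in comps:
            raise ConfigurationError(f"duplicate compartment id {cid!r}")
        try:
            comps[cid] = CompartmentSpec(
                id=cid, kind=d.pop("kind"), region=d.pop("region"),
                resistance=float(d.pop("R")),
                compliance=float(d.pop("C")),
                inertance=float(d.pop("L", 0.0)),
                volume_fraction=float(d.pop("volume_fraction", 0.0)),
                anatomical_height=float(d.pop("height", 0.0)),
                z_node=float(d.pop("z", 0.0)),
                extravascular_source=d.pop("extravascular", "ambient"),
                downstream=d.pop("downstream", None),
                valve=d.pop("valve", None),
                terminal_of=d.pop("terminal_of", None),
                nonlinear_law=d.pop("nonlinear_law", None),
                p_init=float(d.pop("p_init", 10.0)),
            )
        except KeyError as exc:
            raise ConfigurationError(
                f"compartment {cid!r}: missing field {exc}")
        if d:
            raise ConfigurationError(
                f"compartment {cid!r}: unknown fields {sorted(d)}")

    model = NetworkModel(
        name=doc.get("name", "unnamed"),
        model_version=int(doc["model_version"]),
        vessels=vessels,
        compartments=comps,
        chambers=copy.deepcopy(doc.get("chambers", {})),
        cardiac_valves=copy.deepcopy(doc.get("cardiac_valves", {})),
        venous_valves=copy.deepcopy(doc.get("venous_valves", {})),
        regulation=copy.deepcopy(doc.get("regulation", {})),
        coronary=copy.deepcopy(doc.get("coronary", {})),
        intrathoracic=copy.deepcopy(doc.get("intrathoracic",
                                            {"p_supine": -4.0, "delta": 3.0})),
        icp=copy.deepcopy(doc.get("icp", {})),
        tilt_default=copy.deepcopy(doc.get("tilt", {})),
        numerics=copy.deepcopy(doc.get("numerics", {})),
        sites=copy.deepcopy(doc.get("sites", {})),
        blood_density=rho,
        blood_viscosity=mu,
        total_blood_volume=total,
        raw=copy.deepcopy(doc),
    )
    validate_network(model)
    return model


def serialize(model: NetworkModel) -> dict:
    """Round-trippable plain-dict form of the model configuration."""
    return copy.deepcopy(model.raw)


# ----------------------------------------------------------------------------
# Validation
# ----------------------------------------------------------------------------

def validate_network(model: NetworkModel) -> None:
    vessels = model.vessels
    comps = model.compartments
    if model.total_blood_volume <= 0:
        raise ValidationError("total_blood_volume must be positive")

    # --- vessel geometry and tree structure
    roots = []
    for v in vessels.values():
        if v.length <= 0:
            raise ValidationError(f"vessel {v.id}: length must be > 0")
        if v.proximal_radius <= 0 or v.distal_radius <= 0:
            raise ValidationError(f"vessel {v.id}: radii must be > 0")
        if abs(v.longitudinal_projection) > 1.0 + 1e-12:
            raise ValidationError(
                f"vessel {v.id}: |longitudinal_projection| must be <= 1")
        if v.parent_id is None:
            roots.append(v.id)
        elif v.parent_id not in vessels:
            raise ConfigurationError(
                f"vessel {v.id}: unknown parent {v.parent_id}")
    if vessels:
        if len(roots) != 1:
            raise ValidationError(
                f"arterial tree must have exactly one root, found {roots}")
        for v in vessels.values():
            v.child_ids = sorted(c.id for c in vessels.values()
                                 if c.parent_id == v.id)
        # cycle check: walk up from every vessel
        for v in vessels.values():
            seen = set()
            cur = v
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise ValidationError(
                        f"vessel {v.id}: parent chain contains a cycle")
                seen.add(cur.id)
                cur = vessels[cur.parent_id]
        if comps:
            for v in vessels.values():
                arteriole = [c for c in comps.values()
                             if c.terminal_of == v.id]
                if not v.child_ids:
                    if v.terminal_bed_id is None:
                        raise ValidationError(
                            f"leaf vessel {v.id} has no terminal_bed_id")
                    if len(arteriole) != 1:
                        raise ValidationError(
                            f"leaf vessel {v.id} must have exactly one "
                            f"arteriolar compartment, found {len(arteriole)}")
                elif arteriole:
                    raise ValidationError(
                        f"non-leaf vessel {v.id} has an arteriolar "
                        f"compartment")

    # --- compartments
    for c in comps.values():
        if c.kind not in COMPARTMENT_KINDS:
            raise ValidationError(f"compartment {c.id}: unknown kind "
                                  f"{c.kind!r}")
        if c.region not in REGIONS:
            raise ValidationError(f"compartment {c.id}: unknown region "
                                  f"{c.region!r}")
        if c.resistance < 0:
            raise ValidationError(f"compartment {c.id}: resistance >= 0")
        if c.compliance <= 0:
            raise ValidationError(f"compartment {c.id}: compliance > 0")
        if c.inertance < 0:
            raise ValidationError(f"compartment {c.id}: inertance >= 0")
        if c.kind in MICRO_KINDS and c.anatomical_height != 0.0:
            raise ValidationError(
                f"compartment {c.id}: anatomical_height must be 0 for "
                f"{c.kind} compartments (confined microvascular district)")
        if c.extravascular_source not in EXTRAVASCULAR:
            raise ValidationError(
                f"compartment {c.id}: unknown extravascular source "
                f"{c.extravascular_source!r}")
        if c.downstream is not None and c.downstream not in comps \
                and c.downstream not in model.chambers:
            raise ConfigurationError(
                f"compartment {c.id}: unknown downstream {c.downstream!r}")
        if c.valve is not None and c.valve not in model.venous_valves:
            raise ConfigurationError(
                f"compartment {c.id}: unknown valve {c.valve!r}")
        if c.terminal_of is not None and c.terminal_of not in vessels:
            raise ConfigurationError(
                f"compartment {c.id}: unknown terminal vessel "
                f"{c.terminal_of}")

    # micro nodes of one region must share the regional node position
    for region in BODY_REGIONS:
        zset = {c.z_node for c in comps.values()
                if c.region == region and c.kind in {"capillary", "venule"}}
        if len(zset) > 1:
            raise ValidationError(
                f"region {region}: capillary/venule nodes must share one "
                f"z position, found {sorted(zset)}")

    # each populated body region: exactly one capillary, venule, vein
    regions_present = {c.region for c in comps.values()
                       if c.region in BODY_REGIONS}
    for region in regions_present:
        for kind in ("capillary", "venule", "vein"):
            n = sum(1 for c in comps.values()
                    if c.region == region and c.kind == kind)
            if n != 1:
                raise ValidationError(
                    f"region {region}: expected exactly one {kind} "
                    f"compartment, found {n}")

    # closed loop: every compartment chain reaches the right atrium
    if comps:
        for c in comps.values():
            seen = set()
            cur = c
            while True:
                if cur.id in seen:
                    raise ValidationError(
                        f"compartment {c.id}: downstream chain cycles "
                        f"without reaching the heart")
                seen.add(cur.id)
                if cur.downstream is None:
                    raise ValidationError(
                        f"compartment {cur.id}: no downstream connection"
                        f" (closed loop incomplete)")
                if cur.downstream in model.chambers:
                    break
                cur = comps[cur.downstream]

    # volume fractions sum to 1 (when provided at all)
    fr = [c.volume_fraction for c in comps.values()]
    ch_fr = [model.chambers.get(k, {}).get("volume_fraction", 0.0)
             for k in model.chambers]
    tot = sum(fr) + sum(ch_fr)
    if comps and abs(tot - 1.0) > 1e-9:
        raise ValidationError(
            f"volume fractions must sum to 1, got {tot!r}")


# ----------------------------------------------------------------------------
# Blood volume distribution
# ----------------------------------------------------------------------------

def distribute_blood_volume(total: float, fractions: dict) -> dict:
    """Split ``total`` (ml) over compartments by fractional shares.

    Fractions must sum to 1 within 1e-9; the last compartment (in mapping
    order) absorbs the floating-point remainder so the outputs sum to
    ``total`` exactly.
    """
    if not fractions:
        raise ValueError("empty fraction map")
    s = sum(fractions.values())
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {s!r}, expected 1")
    keys = list(fractions)
    out = {k: total * fractions[k] for k in keys[:-1]}
    out[keys[-1]] = total - sum(out.values())
    return out


# ----------------------------------------------------------------------------
# Shipped configurations and fixtures
# ----------------------------------------------------------------------------

def default_config_path(name: str = "healthy_male_reduced") -> str:
    res = importlib.resources.files("orthosim.config") / f"{name}.yaml"
    return str(res)


def load_default(name: str = "healthy_male_reduced") -> NetworkModel:
    """Load one of the shipped reference models."""
    return load_network(default_config_path(name))


def fixture_networks() -> dict:
    """Small fully-parameterized models for solver verification.

    Returns ``single_vessel`` (uniform 1D vessel, no compartments),
    ``symmetric_bifurcation`` (parent + two identical children) and
    ``minimal_closed_loop`` (heart + one artery + one RLC chain).
    """
    from . import _fixtures
    return {
        "single_vessel": _fixtures.single_vessel(),
        "symmetric_bifurcation": _fixtures.symmetric_bifurcation(),
        "minimal_closed_loop": _fixtures.minimal_closed_loop(),
    }
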