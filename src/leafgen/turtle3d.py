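"""Turtle-graphics interpretation of derived strings into labeled 3D meshes.

The turtle carries a position and a right-handed orthonormal frame
(heading ``H``, left ``L``, up ``U``). Symbols drive it through the classic
bracketed-L-system command table:

==========  ====================================================
``F``       draw forward one step (ribbon quad of current width)
``f``       move forward without drawing
``+`` ``-`` yaw left / right about ``U``
``&`` ``^`` pitch down / up about ``L``
``\\`` ``/`` roll left / right about ``H``
``|``       turn around (180 degrees about ``U``)
``[`` ``]`` push / pop the full turtle state
``{ . }``   start polygon, record vertex, close (fan-triangulated)
``!``       set line width
``'``       set color index
==========  ====================================================

A numeric parameter on a symbol overrides the default angle/step
(``+(30)``, ``F(0.5)``). Geometry emitted inside an organ span goes to that
organ instance's mesh; everything else goes to the stem organ (instance 0).
Leaves are renumbered 1..K in order of appearance; branch-class organs get
ids above the leaf range.

Coordinates are right-handed with +Z up. The turtle starts at the origin
heading +Z with left +X and up +Y, so a top-down (looking along -Z)
orthographic camera sees a rosette face-on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lsystem import SPAN_CLOSE, SPAN_OPEN, ORGAN_CLASSES, SymbolString

__all__ = [
    "TurtleState",
    "OrganMesh",
    "PlantModel",
    "TurtleError",
    "interpret",
    "turn",
    "export_obj",
]

_STEM = "stem"


class TurtleError(ValueError):
    """Malformed command string (unbalanced brackets, bad polygon, ...)."""


@dataclass(frozen=True)
class TurtleState:
    """Immutable turtle state: position plus orthonormal (H, L, U) frame."""

    position: np.ndarray
    heading: np.ndarray
    left: np.ndarray
    up: np.ndarray
    step: float = 1.0
    width: float = 0.1
    color_index: int = 0

    @staticmethod
    def initial(step: float = 1.0, width: float = 0.1) -> "TurtleState":
        return TurtleState(
            position=np.zeros(3),
            heading=np.array([0.0, 0.0, 1.0]),
            left=np.array([1.0, 0.0, 0.0]),
            up=np.array([0.0, 1.0, 0.0]),
            step=step,
            width=width,
        )

    def frame(self) -> np.ndarray:
        return np.stack([self.heading, self.left, self.up])


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    theta = np.radians(angle_deg)
    k = axis / np.linalg.norm(axis)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)


def _orthonormalize(h: np.ndarray, l: np.ndarray, u: np.ndarray):
    """Gram-Schmidt cleanup keeping the frame right-handed."""
    h = h / np.linalg.norm(h)
    l = l - (l @ h) * h
    l = l / np.linalg.norm(l)
    u = np.cross(h, l)
    return h, l, u


def turn(state: TurtleState, axis: str, angle: float) -> TurtleState:
    """Rotate the frame about its own H, L or U axis; position unchanged."""
    axes = {"H": state.heading, "L": state.left, "U": state.up}
    if axis not in axes:
        raise ValueError(f"axis must be one of H, L, U; got {axis!r}")
    rot = _rotation_matrix(axes[axis], angle)
    h, l, u = _orthonormalize(rot @ state.heading, rot @ state.left, rot @ state.up)
    return replace(state, heading=h, left=l, up=u)


@dataclass
class OrganMesh:
    """Triangle mesh of a single organ instance."""

    instance_id: int
    organ_class: str
    vertices: list = field(default_factory=list)
    triangles: list = field(default_factory=list)

    def add_triangle(self, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> None:
        area2 = np.linalg.norm(np.cross(b - a, c - a))
        if area2 < 1e-12:
            return  # drop degenerate zero-area triangles
        base = len(self.vertices)
        self.vertices.extend([np.asarray(a, float), np.asarray(b, float), np.asarray(c, float)])
        self.triangles.append((base, base + 1, base + 2))

    @property
    def vertex_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float).reshape(-1, 3)

    @property
    def triangle_array(self) -> np.ndarray:
        return np.asarray(self.triangles, dtype=int).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.triangles)


@dataclass
class PlantModel:
    """Labeled per-organ meshes of a whole plant."""

    organs: list[OrganMesh]

    @property
    def leaf_count(self) -> int:
        return sum(1 for o in self.organs if o.organ_class == "leaf")

    @property
    def leaves(self) -> list[OrganMesh]:
        return [o for o in self.organs if o.organ_class == "leaf"]

    def organ(self, instance_id: int) -> OrganMesh:
        for o in self.organs:
            if o.instance_id == instance_id:
                return o
        raise KeyError(instance_id)

    def triangle_count(self) -> int:
        return sum(len(o) for o in self.organs)


@dataclass
class InterpreterSettings:
    angle: float = 90.0
    step: float = 1.0
    width: float = 0.1


def interpret(
    s: SymbolString,
    settings: InterpreterSettings | None = None,
    *,
    angle: float | None = None,
    step: float | None = None,
    width: float | None = None,
    with_state: bool = False,
) -> PlantModel:
    """Execute the command table over *s* and collect per-organ meshes.

    With ``with_state=True`` returns ``(model, final TurtleState)`` — useful
    for checking the push/pop closure of bracketed subexpressions.

    Raises :class:`TurtleError` for unbalanced ``[ ]``, a ``}`` without
    ``{``, or a closed polygon with fewer than 3 recorded vertices.
    """
    cfg = settings or InterpreterSettings()
    if angle is not None:
        cfg = replace(cfg, angle=angle)
    if step is not None:
        cfg = replace(cfg, step=step)
    if width is not None:
        cfg = replace(cfg, width=width)

    state = TurtleState.initial(step=cfg.step, width=cfg.width)
    stack: list[TurtleState] = []
    polygon: list[np.ndarray] | None = None
    organ_stack: list[tuple[int, str]] = []  # (raw instance id, class)

    meshes: dict[tuple[int, str], OrganMesh] = {}
    order: list[tuple[int, str]] = []

    def current_key() -> tuple[int, str]:
        return organ_stack[-1] if organ_stack else (0, _STEM)

    def mesh() -> OrganMesh:
        key = current_key()
        if key not in meshes:
            meshes[key] = OrganMesh(instance_id=key[0], organ_class=key[1])
            order.append(key)
        return meshes[key]

    def emit_segment(p0: np.ndarray, p1: np.ndarray, st: TurtleState) -> None:
        """Quadrilateral ribbon of the current width, facing the turtle's up."""
        if st.width <= 0:
            return
        half = 0.5 * st.width * st.left
        m = mesh()
        m.add_triangle(p0 - half, p0 + half, p1 + half)
        m.add_triangle(p0 - half, p1 + half, p1 - half)

    class_code_to_name = {float(i + 1): cls for i, cls in enumerate(ORGAN_CLASSES)}

    for sym in s.symbols:
        name = sym.name
        arg = sym.params[0] if sym.params else None
        if name == SPAN_OPEN:
            inst = int(sym.params[0])
            cls = class_code_to_name.get(sym.params[1], "leaf")
            organ_stack.append((inst, cls))
        elif name == SPAN_CLOSE:
            if not organ_stack:
                raise TurtleError("organ-span close without open")
            organ_stack.pop()
        elif name == "F":
            d = arg if arg is not None else state.step
            new_pos = state.position + d * state.heading
            if polygon is None:
                emit_segment(state.position, new_pos, state)
            state = replace(state, position=new_pos)
        elif name == "f":
            d = arg if arg is not None else state.step
            state = replace(state, position=state.position + d * state.heading)
        elif name == "+":
            state = turn(state, "U", arg if arg is not None else cfg.angle)
        elif name == "-":
            state = turn(state, "U", -(arg if arg is not None else cfg.angle))
        elif name == "&":
            state = turn(state, "L", arg if arg is not None else cfg.angle)
        elif name == "^":
            state = turn(state, "L", -(arg if arg is not None else cfg.angle))
        elif name == "\\":
            state = turn(state, "H", arg if arg is not None else cfg.angle)
        elif name == "/":
            state = turn(state, "H", -(arg if arg is not None else cfg.angle))
        elif name == "|":
            state = turn(state, "U", 180.0)
        elif name == "[":
            stack.append(state)
        elif name == "]":
            if not stack:
                raise TurtleError("']' without matching '['")
            state = stack.pop()
        elif name == "{":
            if polygon is not None:
                raise TurtleError("nested '{' polygons are not supported")
            polygon = []
        elif name == ".":
            if polygon is None:
                raise TurtleError("'.' outside a polygon")
            polygon.append(state.position.copy())
        elif name == "}":
            if polygon is None:
                raise TurtleError("'}' without '{'")
            if len(polygon) < 3:
                raise TurtleError("polygon needs at least 3 vertices")
            m = mesh()
            for i in range(1, len(polygon) - 1):
                m.add_triangle(polygon[0], polygon[i], polygon[i + 1])
            polygon = None
        elif name == "!":
            state = replace(state, width=arg if arg is not None else cfg.width)
        elif name == "'":
            state = replace(state, color_index=int(arg) if arg is not None else 0)
        # unknown symbols (grammar nonterminals surviving derivation) are ignored

    if stack:
        raise TurtleError(f"{len(stack)} unclosed '['")
    if polygon is not None:
        raise TurtleError("unclosed '{' polygon")

    # Renumber: leaves 1..K in order of appearance, branches after, stem 0.
    organs: list[OrganMesh] = []
    leaf_id = 0
    leaf_keys = [k for k in order if k[1] == "leaf" and len(meshes[k])]
    branch_keys = [k for k in order if k[1] == "branch" and len(meshes[k])]
    stem_keys = [k for k in order if k[1] == _STEM and len(meshes[k])]
    for key in leaf_keys:
        leaf_id += 1
        m = meshes[key]
        m.instance_id = leaf_id
        organs.append(m)
    next_id = leaf_id
    for key in branch_keys:
        next_id += 1
        m = meshes[key]
        m.instance_id = next_id
        organs.append(m)
    for key in stem_keys:
        m = meshes[key]
        m.instance_id = 0
        organs.append(m)
    model = PlantModel(organs=organs)
    if with_state:
        return model, state
    return model


def export_obj(model: PlantModel, path) -> None:
    """Write the model as a Wavefront OBJ with one object group per organ."""
    import trimesh

    scene = trimesh.Scene()
    for organ in model.organs:
        if not len(organ):
            continue
        mesh = trimesh.Trimesh(
            vertices=organ.vertex_array, faces=organ.triangle_array, process=False
        )
        scene.add_geometry(mesh, node_name=f"{organ.organ_class}_{organ.instance_id}")
    scene.export(str(path))
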