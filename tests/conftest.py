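import numpy as np
import pytest

from leafgen.lsystem import ModuleSymbol, SymbolString, load_grammar, parse_grammar
from leafgen.turtle3d import OrganMesh, PlantModel

ALGAE = "axiom: A\nA -> A B\nB -> A"


@pytest.fixture
def algae_grammar():
    return parse_grammar(ALGAE)


@pytest.fixture
def rosette_grammar():
    from leafgen.dataset_io import preset_path

    return load_grammar(preset_path("rosette"))


@pytest.fixture
def shoot_grammar():
    from leafgen.dataset_io import preset_path

    return load_grammar(preset_path("shoot"))


def symbols(text: str) -> SymbolString:
    """Build a SymbolString from a space-free command string for tests."""
    from leafgen.lsystem import _scan_symbols
    from leafgen.expressions import Expression

    out = []
    for name, args in _scan_symbols(text, 0):
        out.append(ModuleSymbol(name, tuple(float(Expression(a)({})) for a in args)))
    return SymbolString(tuple(out))


def random_triangle_model(rng: np.random.Generator, n_leaves=3, n_triangles=12, with_stem=True):
    """A PlantModel of random triangles spread over a few leaf organs (and
    optionally a stem organ), inside the [-2, 2]^2 x [0, 3] box."""
    organs = []
    ids = list(range(1, n_leaves + 1)) + ([0] if with_stem else [])
    per_organ = {k: [] for k in ids}
    for _ in range(n_triangles):
        k = ids[rng.integers(len(ids))]
        per_organ[k].append(rng.uniform([-2, -2, 0], [2, 2, 3], size=(3, 3)))
    for k in ids:
        mesh = OrganMesh(instance_id=k, organ_class="leaf" if k else "stem")
        for tri in per_organ[k]:
            mesh.add_triangle(*tri)
        organs.append(mesh)
    return PlantModel(organs=[o for o in organs if len(o)])


def random_blob_mask(rng: np.random.Generator, h=32, w=32, n_seeds=3) -> np.ndarray:
    """A random connected-ish binary mask built from overlapping discs."""
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), bool)
    for _ in range(n_seeds):
        cy, cx = rng.uniform(h * 0.25, h * 0.75), rng.uniform(w * 0.25, w * 0.75)
        r = rng.uniform(2, max(3, min(h, w) * 0.25))
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask.astype(np.uint8)
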