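import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cxrline import BinaryMask

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_blob_mask(rng, shape=(32, 32), p=0.25, spacing=(1.0, 1.0)):
    """A random nonempty mask (Bernoulli foreground)."""
    values = rng.random(shape) < p
    if not values.any():
        values[tuple(rng.integers(0, s) for s in shape)] = True
    return BinaryMask(values, spacing)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; no scipy/skimage involvement)
# ---------------------------------------------------------------------------

def flood_fill_components(values, connectivity=8):
    """Brute-force connected components by explicit flood fill."""
    values = np.asarray(values, dtype=bool)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(values, dtype=bool)
    comps = []
    rows, cols = values.shape
    for r in range(rows):
        for c in range(cols):
            if values[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                comp = set()
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr, dc in nbrs:
                        r2, c2 = rr + dr, cc + dc
                        if 0 <= r2 < rows and 0 <= c2 < cols:
                            if values[r2, c2] and not seen[r2, c2]:
                                seen[r2, c2] = True
                                stack.append((r2, c2))
                comps.append(comp)
    return comps


def boundary_points_oracle(values):
    """4-neighbor boundary scan, image border counting as background."""
    values = np.asarray(values, dtype=bool)
    rows, cols = values.shape
    out = set()
    for r in range(rows):
        for c in range(cols):
            if not values[r, c]:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < rows and 0 <= c2 < cols) or not values[r2, c2]:
                    out.add((r, c))
                    break
    return out


def brute_force_assd(pred_values, truth_values, spacing):
    """Direct double loop over all boundary-point pairs."""
    b1 = sorted(boundary_points_oracle(pred_values))
    b2 = sorted(boundary_points_oracle(truth_values))
    sr, sc = spacing
    a1 = np.array([(r * sr, c * sc) for r, c in b1])
    a2 = np.array([(r * sr, c * sc) for r, c in b2])
    d = np.sqrt(((a1[:, None, :] - a2[None, :, :]) ** 2).sum(-1))
    return (d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(b1) + len(b2))
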