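import numpy as np
import pytest

from repquant import SyntheticSpec, generate_section


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A fast-to-render section spec used by most image-level tests."""
    return SyntheticSpec(
        image_shape=(512, 512),
        pixel_size=1.5,
        n_cells_per_zone=(10, 15, 8, 4, 2),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_section(small_spec):
    return generate_section(small_spec)


def brute_force_otsu(hist) -> int:
    """Independent Otsu oracle: exhaustive search over all 255 splits using
    exact rational class statistics (weights and means)."""
    from fractions import Fraction

    hist = [int(h) for h in hist]
    n_total = sum(hist)
    best_t, best_var = None, Fraction(-1)
    for t in range(255):
        n0 = sum(hist[: t + 1])
        n1 = n_total - n0
        if n0 == 0 or n1 == 0:
            continue
        s0 = sum(i * h for i, h in enumerate(hist[: t + 1]))
        s1 = sum(i * h for i, h in enumerate(hist)) - s0
        mu0 = Fraction(s0, n0)
        mu1 = Fraction(s1, n1)
        var = Fraction(n0, n_total) * Fraction(n1, n_total) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def brute_force_clusters(points: np.ndarray, radius: float) -> list[frozenset]:
    """Independent single-linkage oracle: transitive closure of the
    pairwise <= radius relation on the full distance matrix (BFS)."""
    n = len(points)
    if n == 0:
        return []
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    adjacent = d <= radius
    seen = [False] * n
    clusters = []
    for start in range(n):
        if seen[start]:
            continue
        queue, members = [start], set()
        seen[start] = True
        while queue:
            i = queue.pop()
            members.add(i)
            for j in np.nonzero(adjacent[i])[0]:
                if not seen[j]:
                    seen[j] = True
                    queue.append(int(j))
        clusters.append(frozenset(members))
    return clusters
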