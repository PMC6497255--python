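"""Shared fixtures: hand-built skeleton geometries and analytic curves."""

from __future__ import annotations

import numpy as np
import pytest


def _draw(points: list[tuple[int, int]], shape=(40, 40)) -> np.ndarray:
    grid = np.zeros(shape, dtype=bool)
    for r, c in points:
        grid[r, c] = True
    return grid


def line_points(r0, c0, r1, c1):
    """Integer points of an axis/diagonal line (Bresenham-free: only
    horizontal, vertical, or 45-degree lines are used in fixtures)."""
    n = max(abs(r1 - r0), abs(c1 - c0))
    dr = np.sign(r1 - r0)
    dc = np.sign(c1 - c0)
    return [(r0 + i * dr, c0 + i * dc) for i in range(n + 1)]


@pytest.fixture
def straight_skeleton():
    """A single horizontal 20-px line: two terminals, no junctions."""
    return _draw(line_points(20, 5, 20, 24))


@pytest.fixture
def y_skeleton():
    """Y: three straight arms meeting at one fork pixel."""
    pts = (
        line_points(20, 20, 32, 20)  # stem, down
        + line_points(19, 19, 10, 10)  # upper-left arm
        + line_points(19, 21, 10, 30)  # upper-right arm
        + [(20, 20)]
    )
    return _draw(pts)


@pytest.fixture
def plus_skeleton():
    """+: four straight arms meeting at one crossing pixel."""
    pts = (
        line_points(20, 5, 20, 35)
        + line_points(5, 20, 35, 20)
    )
    return _draw(pts)


@pytest.fixture
def ring_skeleton():
    """A diamond-shaped closed 1-px loop (pure cycle, no junctions)."""
    pts = (
        line_points(10, 20, 20, 30)
        + line_points(20, 30, 30, 20)
        + line_points(30, 20, 20, 10)
        + line_points(20, 10, 10, 20)
    )
    return _draw(pts)


@pytest.fixture
def two_fork_tree_skeleton():
    """An acyclic tree with two simple forks: j1 = 4, j2 = 2."""
    pts = (
        line_points(38, 20, 30, 20)  # trunk
        + line_points(29, 19, 20, 10)  # fork 1 left arm, leads to fork 2
        + line_points(29, 21, 20, 30)  # fork 1 right arm (terminal)
        + line_points(19, 9, 10, 0)  # fork 2 left arm (terminal)
        + line_points(19, 11, 10, 20)  # fork 2 right arm (terminal)
        + [(30, 20), (20, 10)]
    )
    return _draw(pts, shape=(40, 40))


def semicircle(radius: float = 50.0, step: float = 1.0) -> np.ndarray:
    """Half circle traversed at approximately unit arc steps (float coords)."""
    n = int(round(np.pi * radius / step)) + 1
    theta = np.linspace(0.0, np.pi, n)
    return np.column_stack([radius * np.sin(theta), radius * np.cos(theta)])


def arc(radius: float, angle: float, step: float = 1.0) -> np.ndarray:
    """Circular arc of given subtended angle at unit arc steps."""
    n = int(round(angle * radius / step)) + 1
    theta = np.linspace(0.0, angle, n)
    return np.column_stack([radius * np.sin(theta), radius * np.cos(theta)])
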