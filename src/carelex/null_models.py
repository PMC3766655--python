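"""Intermittent-silence ("monkey typing") and random-text null models.

The intermittent-silence model imagines a typist striking one of N
non-space keys or the space bar independently at each stroke; the space
(probability q) terminates the current word.  Word lengths are then
geometric, P(L) = q(1-q)^L for L >= 0, and all N^L words of length L are
equiprobable with probability q((1-q)/N)^L — so the rank-frequency curve
is a staircase, flat within each length block, that approximates a power
law with asymptotic log-log slope ln(1-q)/ln N - 1.

The *random text* variant makes the space just another key, so
q = 1/(N+1); its asymptotic slope is -ln(N+1)/ln N (about -1.585 for
N = 2, approaching -1 as N grows).

Huge alphabets (the combined ventilation intervention space has
N = 1946 keys) are handled without materializing any word list: block
boundaries are exact Python integers and only block-level quantities or
log-spaced sample ranks are ever produced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NullModelSpec",
    "BlockRankTable",
    "is_length_pmf",
    "is_rank_frequency_blocks",
    "is_asymptotic_slope",
    "random_text_spec",
    "simulate_monkey",
    "fit_block_table",
    "vc_input_map",
    "pc_input_map",
]


@dataclass(frozen=True)
class NullModelSpec:
    """A typist model: N non-space keys, space probability q, and variant."""

    n_keys: int
    q_space: float
    variant: str = "intermittent_silence"  # or "random_text"

    def __post_init__(self) -> None:
        if self.n_keys < 1:
            raise ValueError("n_keys must be >= 1")
        if not 0.0 < self.q_space < 1.0:
            raise ValueError("q_space must lie in (0, 1)")
        if self.variant not in ("intermittent_silence", "random_text"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "random_text":
            expected = 1.0 / (self.n_keys + 1)
            if not math.isclose(self.q_space, expected, rel_tol=1e-9):
                raise ValueError(
                    f"random_text requires q = 1/(N+1) = {expected}, got {self.q_space}")


@dataclass(frozen=True)
class BlockRankTable:
    """Stepwise rank-frequency structure of a typist model.

    ``blocks`` holds one row per word length L: the rank interval
    [rank_start, rank_end] occupied by the N^L equiprobable words of that
    length and their common probability.  Rank bounds are exact integers
    (rank_end(L) = sum_{j<=L} N^j), never expanded word-by-word.
    """

    spec: NullModelSpec
    blocks: tuple[tuple[int, int, int, float], ...]  # (L, rank_start, rank_end, word_probability)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.blocks, columns=["L", "rank_start", "rank_end",
                                                "word_probability"])
        df.insert(0, "variant", self.spec.variant)
        df.insert(1, "N", self.spec.n_keys)
        df.insert(2, "q", self.spec.q_space)
        return df


def random_text_spec(n_keys: int) -> NullModelSpec:
    """Spec for a purely random typist: the space bar is one of N+1 equal keys."""
    if n_keys < 1:
        raise ValueError("n_keys must be >= 1")
    return NullModelSpec(n_keys=n_keys, q_space=1.0 / (n_keys + 1), variant="random_text")


def is_length_pmf(spec: NullModelSpec, L_max: int) -> tuple[np.ndarray, float]:
    """Word-length law conditioned on non-empty words.

    Returns ``(pmf, tail)`` where ``pmf[k]`` is P(L = k+1 | L >= 1) for
    lengths 1..L_max and ``tail`` is the analytic mass beyond L_max;
    their sum is exactly 1.  The unconditioned law is geometric,
    P(L) = q(1-q)^L for L >= 0.
    """
    if L_max < 1:
        raise ValueError("L_max must be >= 1")
    q = spec.q_space
    lengths = np.arange(1, L_max + 1)
    # condition on L >= 1: divide by 1 - P(0) = 1 - q
    pmf = q * (1.0 - q) ** lengths / (1.0 - q)
    tail = (1.0 - q) ** L_max  # P(L > L_max | L >= 1) = (1-q)^{L_max+1} / (1-q)
    return pmf, float(tail)


def is_rank_frequency_blocks(spec: NullModelSpec, L_max: int) -> BlockRankTable:
    """Blockwise rank-frequency table out to word length ``L_max``.

    All N^L words of length L share probability q((1-q)/N)^L; ranks are
    assigned blockwise by increasing length (shorter words are more
    probable, so blocks are already rank-ordered).
    """
    if L_max < 1:
        raise ValueError("L_max must be >= 1")
    N, q = spec.n_keys, spec.q_space
    if L_max * math.log10(N) > 300:
        raise OverflowError(f"N^L_max = {N}^{L_max} exceeds representable rank bounds")
    blocks = []
    rank_end = 0
    for L in range(1, L_max + 1):
        size = N ** L  # exact integer
        rank_start = rank_end + 1
        rank_end = rank_end + size
        prob = q * ((1.0 - q) / N) ** L
        blocks.append((L, rank_start, rank_end, prob))
    return BlockRankTable(spec=spec, blocks=tuple(blocks))


def is_asymptotic_slope(spec: NullModelSpec) -> float:
    """Closed-form large-rank log-log slope of the typist rank-frequency curve.

    Within block L the probability is q((1-q)/N)^L while rank grows like
    N^L, so ln p is linear in ln r with slope ln(1-q)/ln N - 1.  For the
    random-text variant (q = 1/(N+1)) this reduces to -ln(N+1)/ln N.
    """
    if spec.n_keys == 1:
        raise ValueError("N = 1 is a degenerate alphabet with no rank structure")
    return math.log(1.0 - spec.q_space) / math.log(spec.n_keys) - 1.0


def fit_block_table(table: BlockRankTable, points_per_block: int = 1) -> float:
    """Log-log OLS slope of a block table sampled at log-spaced ranks.

    With one point per block the sample rank is the geometric mean of the
    block's rank interval; more points subdivide each interval evenly in
    log-rank.  Convergence to :func:`is_asymptotic_slope` as L_max grows
    is a model property the tests assert.
    """
    xs, ys = [], []
    for _L, r0, r1, p in table.blocks:
        lr0, lr1 = math.log(r0), math.log(r1)
        if points_per_block == 1:
            xs.append(0.5 * (lr0 + lr1))
            ys.append(math.log(p))
        else:
            for k in range(points_per_block):
                frac = (k + 0.5) / points_per_block
                xs.append(lr0 + frac * (lr1 - lr0))
                ys.append(math.log(p))
    x = np.asarray(xs)
    y = np.asarray(ys)
    slope = float(np.polyfit(x, y, 1)[0])
    return slope


def vc_input_map() -> dict[int, str]:
    """Key -> input map for the 13 non-space volume-controlled keys.

    Twelve setting-change keys (up/down per setting) map pairwise onto
    the six VC settings; the thirteenth key is the fluid bolus.  With
    this map a typed word can touch at most 7 distinct inputs.
    """
    settings = ("tv", "flow", "pause", "fio2", "peep", "rate")
    m: dict[int, str] = {}
    for i, s in enumerate(settings):
        m[2 * i] = s       # up key
        m[2 * i + 1] = s   # down key
    m[12] = "bolus"
    return m


def pc_input_map() -> dict[int, str]:
    """Key -> input map for the 11 non-space pressure-controlled keys (cap 6)."""
    settings = ("pinsp", "itime", "fio2", "peep", "rate")
    m: dict[int, str] = {}
    for i, s in enumerate(settings):
        m[2 * i] = s
        m[2 * i + 1] = s
    m[10] = "bolus"
    return m


def simulate_monkey(spec: NullModelSpec,
                    n_words: int,
                    seed: int,
                    length_metric: str = "keystrokes",
                    input_map: Mapping[int, str] | None = None) -> np.ndarray:
    """Monte-Carlo typist: return ``n_words`` word lengths.

    ``keystrokes`` counts keys struck before the space (0 when two
    spaces are consecutive), so the sample mean estimates (1-q)/q.
    ``distinct_inputs`` maps each key through ``input_map`` and counts
    distinct inputs touched — the "number of inputs changed" reading of
    word length, capped by the number of distinct inputs on the
    keyboard.
    """
    if length_metric not in ("keystrokes", "distinct_inputs"):
        raise ValueError(f"unknown length_metric {length_metric!r}")
    if length_metric == "distinct_inputs" and input_map is None:
        raise ValueError("distinct_inputs metric requires an input_map")
    rng = np.random.default_rng(seed)
    q = spec.q_space
    # geometric(q) counts trials to first success, so lengths are draws - 1
    lengths = rng.geometric(q, size=n_words) - 1
    if length_metric == "keystrokes":
        return lengths
    keys = np.asarray(sorted(input_map))
    if len(keys) != spec.n_keys:
        raise ValueError(f"input_map covers {len(keys)} keys but spec has {spec.n_keys}")
    inputs = {k: v for k, v in input_map.items()}
    out = np.empty(n_words, dtype=np.int64)
    for i, L in enumerate(lengths):
        if L == 0:
            out[i] = 0
            continue
        struck = rng.integers(0, spec.n_keys, size=L)
        out[i] = len({inputs[keys[k]] for k in struck})
    return out
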