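"""Qualitative plumage colour index: ten ordered characters whose integer
state scores sum to a 0-24 index, and longitude-binned cline summaries.

The default scheme gives the four primary diagnostic characters (rufous
wing patch on secondaries, rufous wing patch on primaries, belly
colouration, tail colouration) four states scored 0-3, and six auxiliary
characters three states scored 0-2, so a fully "western" phenotype scores
4*3 + 6*2 = 24 and a fully "southeastern" phenotype scores 0.  Any scheme
with the same shape can be supplied instead (e.g. from a YAML config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlumageScheme",
    "default_scheme",
    "score_individual",
    "score_table",
    "cline_profile",
    "PRIMARY_CHARACTERS",
]

PRIMARY_CHARACTERS = [
    "rufous_patch_secondaries",
    "rufous_patch_primaries",
    "belly_colour",
    "tail_colour",
]

_AUX_CHARACTERS = [
    "crown_colour",
    "throat_iridescence",
    "rump_tinge",
    "uppertail_coverts",
    "wing_covert_edging",
    "undertail_coverts",
]


@dataclass
class PlumageScheme:
    """Ordered characters, each mapping state name -> integer score."""

    characters: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for char, states in self.characters.items():
            if not states:
                raise ValueError(f"character {char} has no states")
            if len(set(states)) != len(states):
                raise ValueError(f"duplicate state names in {char}")
            if min(states.values()) != 0:
                raise ValueError(f"character {char} minimum score must be 0")

    @property
    def character_names(self) -> list[str]:
        return list(self.characters)

    def maximum(self, character: str) -> int:
        return max(self.characters[character].values())

    @property
    def total_maximum(self) -> int:
        return sum(self.maximum(c) for c in self.characters)

    def state_for_score(self, character: str, score: int) -> str:
        for state, s in self.characters[character].items():
            if s == score:
                return state
        raise KeyError(f"no state of {character} scores {score}")


def default_scheme() -> PlumageScheme:
    chars: dict[str, dict[str, int]] = {}
    four = {"absent": 0, "trace": 1, "partial": 2, "extensive": 3}
    chars["rufous_patch_secondaries"] = dict(four)
    chars["rufous_patch_primaries"] = dict(four)
    chars["belly_colour"] = {"emerald_green": 0, "mixed_green": 1,
                             "golden_tinge": 2, "golden_green": 3}
    chars["tail_colour"] = {"steel_blue": 0, "blue_purple": 1,
                            "mixed_rufous_blue": 2, "rufous_brown": 3}
    three = {"southeastern": 0, "intermediate": 1, "western": 2}
    for aux in _AUX_CHARACTERS:
        chars[aux] = dict(three)
    return PlumageScheme(chars)


def score_individual(states: dict[str, str],
                     scheme: PlumageScheme | None = None) -> int:
    """Sum of per-character state scores; errors name the offending character."""
    scheme = scheme or default_scheme()
    total = 0
    for char in scheme.character_names:
        if char not in states:
            raise ValueError(f"missing character: {char}")
        state = states[char]
        if state not in scheme.characters[char]:
            raise ValueError(f"unknown state {state!r} for character {char}")
        total += scheme.characters[char][state]
    return total


def score_table(df: pd.DataFrame,
                scheme: PlumageScheme | None = None) -> pd.DataFrame:
    """Append an ``index`` column to a trait table (id, longitude, states)."""
    scheme = scheme or default_scheme()
    out = df.copy()
    out["index"] = [
        score_individual({c: row[c] for c in scheme.character_names}, scheme)
        for _, row in df.iterrows()
    ]
    return out


def cline_profile(df: pd.DataFrame, n_bins: int = 10,
                  value_col: str = "index",
                  per_character: bool = False,
                  scheme: PlumageScheme | None = None) -> pd.DataFrame:
    """Equal-width longitude bins with per-bin mean, sd and count.

    With ``per_character`` the four primary diagnostic characters are also
    profiled (their numeric state scores)."""
    if "longitude" not in df.columns:
        raise ValueError("trait table needs a longitude column")
    lon = df["longitude"].to_numpy(dtype=float)
    if lon.max() == lon.min():
        raise ValueError("zero-width longitude range")
    edges = np.linspace(lon.min(), lon.max(), n_bins + 1)
    which = np.clip(np.digitize(lon, edges[1:-1]), 0, n_bins - 1)
    scheme = scheme or default_scheme()
    targets = [value_col]
    data = {value_col: df[value_col].to_numpy(dtype=float)}
    if per_character:
        for char in PRIMARY_CHARACTERS:
            if char in df.columns:
                data[char] = np.array(
                    [scheme.characters[char][s] for s in df[char]], dtype=float)
                targets.append(char)
    rows = []
    for b in range(n_bins):
        mask = which == b
        row = {"bin": b, "lon_lo": edges[b], "lon_hi": edges[b + 1],
               "n": int(mask.sum())}
        for t in targets:
            vals = data[t][mask]
            row[f"mean_{t}"] = float(vals.mean()) if len(vals) else np.nan
            row[f"sd_{t}"] = float(vals.std(ddof=0)) if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
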