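"""Canonical behaviour taxonomy: 12 behaviours in 3 functional groups.

The taxonomy follows the standard domestic-cat ethogram used in
accelerometry studies: four sedentary postures, three eating/locomotive
gaits and five hunting actions. Behaviour names are lowercase with
underscores and are the only labels accepted anywhere in the package.
"""

from __future__ import annotations

BEHAVIOUR_GROUPS: dict[str, tuple[str, ...]] = {
    "sedentary": ("lying", "sitting", "grooming", "watching"),
    "eating_locomotive": ("eating_drinking", "walking", "trotting"),
    "hunting": ("galloping", "jumping", "pouncing", "swatting", "biting_holding"),
}

#: All 12 behaviours in canonical order (group order, then within-group order).
BEHAVIOURS: tuple[str, ...] = tuple(
    b for group in BEHAVIOUR_GROUPS.values() for b in group
)

#: Treatment conditions: prey-protector bib fitted (bib_on) or not (bib_off).
TREATMENTS: tuple[str, ...] = ("bib_off", "bib_on")

_GROUP_OF = {b: g for g, members in BEHAVIOUR_GROUPS.items() for b in members}


def group_of(behaviour: str) -> str:
    """Return the functional group of a behaviour.

    Raises
    ------
    KeyError
        If ``behaviour`` is not in the canonical taxonomy.
    """
    return _GROUP_OF[behaviour]


def validate_behaviour(behaviour: str) -> str:
    if behaviour not in _GROUP_OF:
        raise ValueError(
            f"unknown behaviour {behaviour!r}; expected one of {sorted(BEHAVIOURS)}"
        )
    return behaviour


def validate_treatment(treatment: str) -> str:
    if treatment not in TREATMENTS:
        raise ValueError(
            f"unknown treatment {treatment!r}; expected one of {TREATMENTS}"
        )
    return treatment
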