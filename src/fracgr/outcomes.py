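"""Fracture-outcome classification.

Four nested outcome definitions are used throughout the package:

``any``
    every recorded fracture site;
``osteoporotic``
    the Kanis-type osteoporotic-site set (clinical vertebral, ribs, pelvis,
    humerus, clavicle, scapula, sternum, hip, other femoral, tibia, fibula,
    distal forearm/wrist);
``MOF``
    major osteoporotic fracture (hip, clinical vertebral, proximal humerus,
    distal forearm/wrist);
``hip``
    hip fracture only.

The site vocabulary and its class assignment live in an editable YAML table
(``data/sites.yaml``).  Each site is tagged with the most specific class it
belongs to, and the nesting ``hip ⊂ MOF ⊂ osteoporotic ⊂ any`` is derived
from the tag, so the nesting invariant holds by construction for any edited
table.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

#: Outcome names ordered from broadest to narrowest.
OUTCOME_ORDER: tuple[str, ...] = ("any", "osteoporotic", "MOF", "hip")

#: Rank of each outcome class in the nesting (higher = more specific).
_CLASS_RANK = {name: i for i, name in enumerate(OUTCOME_ORDER)}


class UnknownSiteError(KeyError):
    """Raised when a fracture site code is not in the controlled vocabulary."""


class SiteMap:
    """Site vocabulary plus the nested outcome classification.

    Parameters
    ----------
    site_class
        Mapping from site code to the most specific outcome class
        (one of ``OUTCOME_ORDER``) the site belongs to.
    """

    def __init__(self, site_class: dict[str, str]):
        for site, cls in site_class.items():
            if cls not in _CLASS_RANK:
                raise ValueError(f"site {site!r}: unknown outcome class {cls!r}")
        self.site_class = dict(site_class)

    @classmethod
    def load(cls, path: str | Path | None = None) -> "SiteMap":
        """Load the site table from YAML; ``None`` loads the packaged default."""
        if path is None:
            text = (resources.files("fracgr") / "data" / "sites.yaml").read_text()
        else:
            text = Path(path).read_text()
        doc = yaml.safe_load(text)
        return cls(doc["sites"])

    @property
    def sites(self) -> set[str]:
        return set(self.site_class)

    def outcome_sites(self, outcome: str) -> set[str]:
        """All site codes counted under *outcome*."""
        if outcome not in _CLASS_RANK:
            raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOME_ORDER}")
        rank = _CLASS_RANK[outcome]
        return {s for s, c in self.site_class.items() if _CLASS_RANK[c] >= rank}

    def classify(self, site: str) -> set[str]:
        """Return every outcome set containing *site* (``any`` always included)."""
        try:
            cls = self.site_class[site]
        except KeyError:
            raise UnknownSiteError(
                f"unknown fracture site {site!r}; vocabulary: {sorted(self.site_class)}"
            ) from None
        return set(OUTCOME_ORDER[: _CLASS_RANK[cls] + 1])


_DEFAULT: SiteMap | None = None


def default_site_map() -> SiteMap:
    """The packaged site table (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = SiteMap.load()
    return _DEFAULT


def classify_fracture(site: str, site_map: SiteMap | None = None) -> set[str]:
    """Outcome sets containing *site*; errors on unknown codes."""
    return (site_map or default_site_map()).classify(site)


def first_event_time(
    events: list[tuple[str, float]],
    outcome: str,
    site_map: SiteMap | None = None,
) -> float | None:
    """Time of the first fracture qualifying for *outcome*, or ``None``.

    Only the first qualifying fracture per person is counted; later events
    are ignored by the survival analysis.
    """
    sites = (site_map or default_site_map()).outcome_sites(outcome)
    times = [t for site, t in events if site in sites]
    return min(times) if times else None


def format_events(events: list[tuple[str, float]]) -> str:
    """Serialize fracture events as ``site:time;site:time`` (times in years)."""
    return ";".join(f"{site}:{t:.12g}" for site, t in events)


def parse_events(text: str | float | None) -> list[tuple[str, float]]:
    """Inverse of :func:`format_events`; empty/NaN input gives ``[]``."""
    if text is None or (isinstance(text, float)) or not str(text).strip():
        return []
    out = []
    for token in str(text).split(";"):
        site, _, t = token.rpartition(":")
        out.append((site, float(t)))
    return out
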