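"""Channel montage: the 53-channel optode layout and its cortical-region map.

The default montage covers five regions of the fronto-parieto-temporal
cortex measured by a 53-channel continuous-wave fNIRS device (channel 28 at
Cz of the international 10-20 system): the bilateral supplementary motor
area (SMA, 20 channels), the primary motor cortex (M1, 11 channels), the
primary somatosensory cortex (S1, 4 channels), Wernicke's area (14
channels), and the somatosensory association cortex (SAC, 4 channels).

Hemisphere labels are not part of the default montage (the source layout
does not pin individual channels to a hemisphere); users who want a
hemispheric node set for connectivity analysis can supply their own config
in the same plain-text format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

REGIONS = ("SMA", "M1", "S1", "Wernicke", "SAC")

_EXPECTED_SIZES = {"SMA": 20, "M1": 11, "S1": 4, "Wernicke": 14, "SAC": 4}


@dataclass(frozen=True)
class ChannelMontage:
    """Immutable channel -> region (and optional hemisphere) assignment.

    Parameters
    ----------
    region_map : dict
        Mapping channel id (1-based int) to region label.
    hemisphere_map : dict
        Mapping channel id to ``"left"``, ``"right"``, ``"midline"`` or
        ``"unspecified"``.
    reference_note : str
        Free-text provenance note.
    """

    region_map: dict[int, str]
    hemisphere_map: dict[int, str] = field(default_factory=dict)
    reference_note: str = ""

    def __post_init__(self) -> None:
        regions = set(self.region_map.values())
        unknown = regions - set(REGIONS)
        # user-supplied montages may define extra node labels (e.g. FEF);
        # only the default loader enforces the five-region partition
        for ch in self.region_map:
            if not isinstance(ch, int) or ch < 1:
                raise ValueError(f"channel ids must be positive integers, got {ch!r}")
        if unknown and not all(isinstance(r, str) and r for r in unknown):
            raise ValueError(f"bad region labels: {unknown}")

    @property
    def channels(self) -> list[int]:
        return sorted(self.region_map)

    @property
    def regions(self) -> list[str]:
        seen: list[str] = []
        for ch in self.channels:
            r = self.region_map[ch]
            if r not in seen:
                seen.append(r)
        return seen

    def region_of(self, channel: int) -> str:
        try:
            return self.region_map[channel]
        except KeyError:
            raise KeyError(
                f"channel {channel} not in montage (channels 1..{len(self.region_map)})"
            ) from None

    def hemisphere_of(self, channel: int) -> str:
        self.region_of(channel)  # validate channel
        return self.hemisphere_map.get(channel, "unspecified")

    def node_of(self, channel: int, hemispheric: bool = False) -> str:
        """Node label for connectivity analysis.

        With ``hemispheric`` set, channels with a left/right assignment map
        to ``L-<region>`` / ``R-<region>`` nodes (midline or unspecified
        channels keep the plain region label).
        """
        region = self.region_of(channel)
        if not hemispheric:
            return region
        hemi = self.hemisphere_of(channel)
        prefix = {"left": "L-", "right": "R-"}.get(hemi, "")
        return f"{prefix}{region}"

    def node_labels(self, hemispheric: bool = False) -> list[str]:
        """Distinct node labels in order of first channel occurrence."""
        return list(dict.fromkeys(self.node_of(ch, hemispheric) for ch in self.channels))

    def node_channels(self, hemispheric: bool = False) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for ch in self.channels:
            out.setdefault(self.node_of(ch, hemispheric), []).append(ch)
        return out


def roi_channels(montage: ChannelMontage, region: str) -> list[int]:
    """Sorted channel ids assigned to ``region``.

    Raises
    ------
    KeyError
        If ``region`` is not a label of this montage; the message lists the
        valid labels.
    """
    labels = set(montage.region_map.values())
    if region not in labels:
        raise KeyError(
            f"unknown region {region!r}; valid regions: {sorted(labels)}"
        )
    return sorted(ch for ch, r in montage.region_map.items() if r == region)


def load_montage(path: str | Path) -> ChannelMontage:
    """Parse a plain-text montage config: ``<channel> <region> [hemisphere]``."""
    region_map: dict[int, str] = {}
    hemi_map: dict[int, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise ValueError(f"{path}:{lineno}: expected '<channel> <region> [hemisphere]'")
        ch = int(parts[0])
        if ch in region_map:
            raise ValueError(f"{path}:{lineno}: duplicate channel {ch}")
        region_map[ch] = parts[1]
        if len(parts) == 3:
            hemi_map[ch] = parts[2]
    return ChannelMontage(region_map, hemi_map, reference_note=f"loaded from {path}")


def default_montage() -> ChannelMontage:
    """The packaged 53-channel montage (channel 28 at Cz).

    Validates the five-region partition: SMA=20, M1=11, S1=4, Wernicke=14,
    SAC=4 channels, disjoint and exhaustive over channels 1..53.
    """
    with resources.as_file(
        resources.files("nirstates.data").joinpath("montage_53.cfg")
    ) as p:
        m = load_montage(p)
    if sorted(m.region_map) != list(range(1, 54)):
        raise RuntimeError("packaged montage must cover channels 1..53 exactly")
    sizes = {r: len(roi_channels(m, r)) for r in REGIONS}
    if sizes != _EXPECTED_SIZES:
        raise RuntimeError(f"packaged montage region sizes {sizes} != {_EXPECTED_SIZES}")
    return ChannelMontage(
        m.region_map, m.hemisphere_map, reference_note="53-channel default; channel 28 at Cz"
    )
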