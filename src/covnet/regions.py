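"""Cortical parcellation labels.

The Desikan-Killiany atlas divides each hemisphere into 34 gyral-based
regions, giving the 68 cortical nodes conventionally used for
thickness-based structural covariance networks.
"""

from __future__ import annotations

_DK_34 = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

#: The 68 Desikan-Killiany cortical labels, left hemisphere first.
DESIKAN_KILLIANY_68: tuple[str, ...] = tuple(
    f"{hemi}_{name}" for hemi in ("lh", "rh") for name in _DK_34
)


def default_module_assignment(n_regions: int, n_modules: int = 4) -> tuple[int, ...]:
    """Partition ``n_regions`` label positions into contiguous blocks.

    Used as the default community structure of the synthetic cohort
    generator: regions within a block share elevated covariance, mimicking
    the lobar/system organisation of real structural covariance networks.
    """
    if n_modules < 1 or n_modules > n_regions:
        raise ValueError("n_modules must be in [1, n_regions]")
    base, extra = divmod(n_regions, n_modules)
    assignment: list[int] = []
    for m in range(n_modules):
        assignment.extend([m] * (base + (1 if m < extra else 0)))
    return tuple(assignment)
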