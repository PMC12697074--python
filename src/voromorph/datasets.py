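"""Bundled reference inputs."""

from importlib import resources

from .geometry import SeedSet, parse_seed_coordinates

__all__ = ["capsule_seed_points"]


def capsule_seed_points() -> SeedSet:
    """The 22 labelled pore-centre coordinates (P1-P22) digitised from the
    vertical capsule section, as used for the worked Voronoi-verification
    example.  Units are image pixels of the original micrograph export
    (screen convention, hence the negative y values)."""
    text = (
        resources.files("voromorph")
        .joinpath("data/capsule_seed_points.txt")
        .read_text(encoding="utf-8")
    )
    return parse_seed_coordinates(text)
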