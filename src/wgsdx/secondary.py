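"""Medically actionable secondary-findings screen against a 56-gene panel."""

from __future__ import annotations

from typing import List, Optional, Sequence

from .models import LOF_EFFECTS, GenePanelEntry, SecondaryFinding, SequenceVariant

__all__ = ["EmptyPanelError", "screen_secondary", "load_default_panel"]


class EmptyPanelError(ValueError):
    pass


def screen_secondary(
    case_variants: Sequence[SequenceVariant],
    panel: Sequence[GenePanelEntry],
    consent: bool,
) -> List[SecondaryFinding]:
    """Return panel-gene variants with LoF impact or a pathogenic assertion.

    Unlike the primary analysis, UTR/intronic/intergenic variants are
    eligible when asserted pathogenic. Consent only controls the
    ``returnable`` flag; the finding set itself is consent-independent so a
    laboratory audit trail is preserved. Idempotent and restricted to panel
    genes by construction.
    """
    if not panel:
        raise EmptyPanelError("secondary-findings panel is empty")
    panel_genes = {entry.gene for entry in panel}
    findings: List[SecondaryFinding] = []
    for v in case_variants:
        ann = v.annotation
        if ann is None or ann.gene not in panel_genes:
            continue
        asserted = any(a in {"pathogenic", "likely_pathogenic"} for a in ann.assertions.values())
        if ann.effect_class in LOF_EFFECTS:
            basis = "LoF"
        elif asserted:
            basis = "asserted_pathogenic"
        else:
            continue
        findings.append(
            SecondaryFinding(
                case_id=v.case_id, variant=v, gene=ann.gene, basis=basis, returnable=consent
            )
        )
    return findings


def load_default_panel() -> List[GenePanelEntry]:
    """The packaged 56-gene actionable panel (2013 guideline vintage)."""
    from .io import read_panel
    from importlib.resources import files

    return read_panel(files("wgsdx.data").joinpath("acmg56_panel.tsv"))
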