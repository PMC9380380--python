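"""Chronic pancreatitis clinical-subtype assignment.

Hereditary CP (HCP) requires three or more affected family members spanning
at least two generations; familial CP (FCP) is a positive family history that
falls short of the HCP criteria; alcoholic CP (ACP) is attributed to chronic
excessive alcohol intake (>= 80 g/d male, >= 60 g/d female, >= 2 years);
idiopathic CP (ICP) requires neither a family history nor any obvious
external risk factor.  The four subtypes are mutually exclusive; pedigree
evidence takes precedence over the alcohol flag.
"""

from __future__ import annotations

from typing import Optional

from ..types import PedigreeSummary, Subtype, ValidationError


def classify_subtype(
    pedigree: PedigreeSummary,
    *,
    family_history: Optional[bool] = None,
    alcohol_excess: bool = False,
    other_external_factor: bool = False,
    claimed: Optional[Subtype] = None,
) -> Subtype:
    """Assign one of the four CP subtypes.

    ``family_history`` defaults to what the pedigree implies (two or more
    affected members).  ``claimed`` lets a caller assert the subtype recorded
    upstream; a mismatch (e.g. ICP claimed for an alcohol-exposed case) is a
    validation error, as is a pedigree contradicting an explicit
    ``family_history=False``.
    """
    implied_history = pedigree.n_affected >= 2
    if family_history is False and implied_history:
        raise ValidationError(
            "family_history=False contradicts a pedigree with "
            f"{pedigree.n_affected} affected members")
    history = implied_history if family_history is None else family_history

    if pedigree.n_affected >= 3 and pedigree.n_generations >= 2:
        subtype = Subtype.HCP
    elif history:
        subtype = Subtype.FCP
    elif alcohol_excess:
        subtype = Subtype.ACP
    elif other_external_factor:
        raise ValidationError(
            "an external risk factor other than alcohol excludes ICP but has "
            "no subtype of its own in this scheme")
    else:
        subtype = Subtype.ICP

    if claimed is not None and claimed is not subtype:
        raise ValidationError(
            f"claimed subtype {claimed.value} contradicts the evidence "
            f"({subtype.value})")
    return subtype
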