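"""Rule-based MS/MS prediction for picolinyl-derivatized sterols.

Collision-induced dissociation of derivatized sterols is dominated by the
neutral loss of picolinic acid (PA, 123.0320 Da) and the sodiated PA
derivate ion.  The prediction rule emits:

* the sterol skeleton ion — precursor minus one neutral PA
  ([M+H−PA]+ for monohydroxysterols, [M+Na−PA]+ for di- and
  polyhydroxysterols, following the precursor adduct);
* the derivate ion [PA+Na]+ at 146.0212 Th;
* for polyhydroxysterols, additional sequential PA losses as optional
  low-intensity annotated peaks (not used by the rule score).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import PICOLINIC_ACID, SODIUM_CATION, NotDerivatizableError
from .spectra import Spectrum

__all__ = ["FragmentRuleSet", "DERIVATE_ION_MZ", "predict_fragments"]

#: [PA+Na]+ m/z — picolinic acid plus a sodium cation.
DERIVATE_ION_MZ = PICOLINIC_ACID + SODIUM_CATION  # 146.021248


@dataclass(frozen=True)
class FragmentRuleSet:
    """Tunable pieces of the fragmentation rule."""

    pa_mass: float = PICOLINIC_ACID
    derivate_mz: float = DERIVATE_ION_MZ
    skeleton_intensity: float = 100.0
    derivate_intensity: float = 50.0
    extra_loss_intensity: float = 10.0
    emit_sequential_losses: bool = True


DEFAULT_RULES = FragmentRuleSet()


def predict_fragments(entry, rules: FragmentRuleSet = DEFAULT_RULES) -> Spectrum:
    """Predict the characteristic fragment spectrum of a library entry.

    ``entry`` needs ``mz`` and ``compound.n_hydroxyl``.  Peaks are annotated
    ``"skeleton"``, ``"derivate"`` or ``"extra_loss"``.
    """
    n_oh = int(entry.compound.n_hydroxyl)
    if not 1 <= n_oh <= 5:
        raise NotDerivatizableError(f"hydroxyl count {n_oh} outside 1..5")
    precursor = float(entry.mz)
    skeleton = precursor - rules.pa_mass
    mz = [skeleton, rules.derivate_mz]
    inten = [rules.skeleton_intensity, rules.derivate_intensity]
    ann = ["skeleton", "derivate"]
    if rules.emit_sequential_losses:
        for k in range(2, n_oh + 1):
            extra = precursor - k * rules.pa_mass
            if extra <= rules.derivate_mz:
                break
            mz.append(extra)
            inten.append(rules.extra_loss_intensity)
            ann.append("extra_loss")
    return Spectrum(np.array(mz), np.array(inten), annotations=tuple(ann),
                    metadata={"predicted": "rule"})
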