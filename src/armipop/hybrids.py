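"""ITS1 diagnostic-band classifier for putative Helicoverpa hybrids.

The species-specific ITS1 amplicons differ in length — ~147 bp for
H. armigera, ~334 bp for H. zea — so an individual showing both bands on
a gel is a hybrid candidate.  A candidate is only called a putative
hybrid when sequencing confirms each band as the expected species; a
band confirmed as the wrong species, or at the wrong size, marks primer
nonspecificity and the individual is left indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ARMIGERA_BAND = 147
ZEA_BAND = 334

ARMIGERA = "armigera"
ZEA = "zea"
PUTATIVE_HYBRID = "putative_hybrid"
INDETERMINATE = "indeterminate"


@dataclass
class BandRecord:
    """One individual's gel bands and per-band sequencing confirmations.

    ``confirmations`` maps an observed band length to ``"armigera"``,
    ``"zea"``, ``"nonspecific"`` or ``"untested"``.
    """

    individual: str
    bands: frozenset[int]
    confirmations: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bands = frozenset(int(b) for b in self.bands)
        if any(b <= 0 for b in self.bands):
            raise ValueError("band lengths must be positive")
        unknown = set(self.confirmations) - set(self.bands)
        if unknown:
            raise ValueError(f"confirmations for unobserved bands: {sorted(unknown)}")

    def confirmation(self, band: int) -> str:
        return self.confirmations.get(band, "untested")


def _near(band: int, target: int, tol: int) -> bool:
    return abs(band - target) <= tol


def classify(record: BandRecord, tol: int = 10) -> str:
    """Classify one individual from its bands (±``tol`` bp gel tolerance).

    One band near 147 bp → armigera; near 334 bp → zea.  Both present →
    putative hybrid, but only when neither band's sequencing confirmation
    contradicts its species; any nonspecific or cross-species
    confirmation, or a band matching neither target, → indeterminate.
    """
    if not record.bands:
        raise ValueError(f"{record.individual}: no bands to classify")
    arm = [b for b in record.bands if _near(b, ARMIGERA_BAND, tol)]
    zea = [b for b in record.bands if _near(b, ZEA_BAND, tol)]
    stray = record.bands - set(arm) - set(zea)
    if stray:
        return INDETERMINATE
    if arm and zea:
        arm_ok = all(record.confirmation(b) in {ARMIGERA, "untested"} for b in arm)
        zea_ok = all(record.confirmation(b) in {ZEA, "untested"} for b in zea)
        confirmed = any(record.confirmation(b) == ARMIGERA for b in arm) and any(
            record.confirmation(b) == ZEA for b in zea
        )
        if confirmed and arm_ok and zea_ok:
            return PUTATIVE_HYBRID
        return INDETERMINATE
    if arm:
        return ARMIGERA if all(
            record.confirmation(b) in {ARMIGERA, "untested"} for b in arm
        ) else INDETERMINATE
    return ZEA if all(
        record.confirmation(b) in {ZEA, "untested"} for b in zea
    ) else INDETERMINATE


def hybrid_frequency(records, tol: int = 10) -> tuple[int, int, float]:
    """(hybrids, total, percent) over a collection of band records."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    hybrids = sum(classify(r, tol) == PUTATIVE_HYBRID for r in records)
    total = len(records)
    return hybrids, total, 100.0 * hybrids / total
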