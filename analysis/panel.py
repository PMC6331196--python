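"""The simulated crossing panel shared by the numbered analysis scripts.

Nine cross designs: the reference cross IPO323 x IPO94269 (chr18 and chr20
unpaired, inherited from IPO323) plus the eight whole-chromosome deletion
derivatives of IPO323, each adding one reciprocally unpaired chromosome
inherited from IPO94269.  The generating mechanism is the female-restricted
drive with full penetrance for chr15-chr21 and zero penetrance for chr14
(the one supernumerary chromosome without observable drive), a per-instance
loss probability of 0.037 per meiosis and a small non-disjunction rate that
reproduces occasional biparental disomies of paired chromosomes.
"""

from __future__ import annotations

from octadrive.cross_simulator import CrossConfig, build_cross, simulate_experiment
from octadrive.strains import SUPERNUMERARY_CHROMOSOMES, ipo323, ipo323_deletion, ipo94269

N_ASCI_PER_CROSS = 40
LOSS_RATE = 0.037
NONDISJUNCTION_RATE = 0.015
DRIVE_PENETRANCE = {"chr14": 0.0}  # chr15..chr21 default to 1.0
BASE_SEED = 20181213


def cross_designs():
    """(name, parent1, parent2) for the nine panel crosses."""
    designs = [("IPO323xIPO94269", ipo323(), ipo94269())]
    for chrom in SUPERNUMERARY_CHROMOSOMES:
        designs.append(
            (f"IPO323d{chrom}xIPO94269", ipo323_deletion(chrom), ipo94269())
        )
    return designs


def simulate_panel(mechanism: str = "female_drive"):
    """Simulate every cross; yields (name, config, pairing, octads)."""
    for i, (name, p1, p2) in enumerate(cross_designs()):
        config = CrossConfig(
            parent1=p1,
            parent2=p2,
            mechanism=mechanism,
            loss_rate=LOSS_RATE,
            nondisjunction_rate=NONDISJUNCTION_RATE,
            drive_penetrance=DRIVE_PENETRANCE,
            n_asci=N_ASCI_PER_CROSS,
            seed=BASE_SEED + i,
        )
        yield name, config, build_cross(p1, p2), simulate_experiment(config)
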