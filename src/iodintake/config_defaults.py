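"""Example salt-policy and DRI configurations.

The market shares and concentrations that the underlying salt-iodisation
assumptions state publicly are used directly: 95 % of consumed bread
contains iodised bakery salt at an average 58 mg I/kg salt; other foods use
low-iodine salt at an average 20 mg I/kg; two big pizza brands give a ~40 %
market share with half of the pizza's salt attributable to added iodised
salt; meat products and breakfast crackers 0.5 %; cookies, cakes and sweet
pies 1 %.  The never-user proportions by age/sex band, the per-food-group
discretionary use fractions and the salt amounts added per 100 g food are
not public at cell level and the values here are synthetic illustrations.

EAR/UL values are user configuration; the numbers below are illustrative
entries in the style of the IOM EARs and SCF ULs for iodine.
"""

from __future__ import annotations

from .datatypes import (
    DiscretionaryGroupPolicy,
    DRIBand,
    DRITable,
    ManufacturerGroupPolicy,
    SaltPolicy,
)

HIGH_IODISED_SALT = 58.0  # bakery salt, mg I / kg salt
LOW_IODISED_SALT = 20.0  # all other iodised salt, mg I / kg salt


def default_policy() -> SaltPolicy:
    never = {}
    for (lo, hi), p in {
        (7, 8): 0.45, (9, 13): 0.40, (14, 18): 0.35,
        (19, 30): 0.30, (31, 50): 0.25, (51, 69): 0.25,
    }.items():
        never[(lo, hi, "male")] = p
        never[(lo, hi, "female")] = p + 0.05
    return SaltPolicy(
        manufacturer={
            "bread": ManufacturerGroupPolicy(market_share=0.95, iodine_conc=HIGH_IODISED_SALT),
            "pizza": ManufacturerGroupPolicy(
                market_share=0.40, iodine_conc=LOW_IODISED_SALT, salt_fraction=0.5
            ),
            "meat_products": ManufacturerGroupPolicy(
                market_share=0.005, iodine_conc=LOW_IODISED_SALT
            ),
            "crackers": ManufacturerGroupPolicy(market_share=0.005, iodine_conc=LOW_IODISED_SALT),
            "cookies": ManufacturerGroupPolicy(market_share=0.01, iodine_conc=LOW_IODISED_SALT),
        },
        discretionary_iodine_conc=LOW_IODISED_SALT,
        discretionary_groups={
            "potatoes": DiscretionaryGroupPolicy(added_amount=1.0, use_fraction=0.5),
            "vegetables": DiscretionaryGroupPolicy(added_amount=1.0, use_fraction=0.4),
            "meat": DiscretionaryGroupPolicy(added_amount=0.5, use_fraction=0.3),
        },
        never_user_proportions=never,
    )


def default_dri() -> DRITable:
    bands = []
    for sex in ("male", "female"):
        bands += [
            DRIBand(7, 8, sex, ear=65.0, ul=300.0),
            DRIBand(9, 13, sex, ear=73.0, ul=450.0),
            DRIBand(14, 18, sex, ear=95.0, ul=500.0),
            DRIBand(19, 69, sex, ear=95.0, ul=600.0),
        ]
    return DRITable(bands=bands)
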