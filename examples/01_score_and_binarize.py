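"""Score drug sensitivities and binarize target profiles for a tiny screen.

Each drug's IC50 (dose halving tumor-cell viability) becomes a score in
[0, 1] anchored at Cmax (clinically achievable, score 1) and MaxDose
(highest screened dose, score 0).  Each drug's EC50 vector (dose
half-inhibiting each kinase) is thresholded to the binary set of targets
plausibly responsible for the kill: log10(EC50) within [0, 2]*log10(IC50).
"""

from timkit import BinarizationConfig, DrugProfile, binarize_targets, scale_sensitivity

cfg = BinarizationConfig(alpha=0.0, beta=2.0)
drugs = [
    # a potent multi-kinase inhibitor: IC50 well below Cmax
    DrugProfile("dasatinib-like", ec50={0: 4.0, 1: 80.0, 2: 6000.0},
                ic50=12.0, cmax=100.0, maxdose=10_000.0),
    # mid-range responder
    DrugProfile("sunitinib-like", ec50={1: 40.0, 3: 900.0},
                ic50=800.0, cmax=100.0, maxdose=10_000.0),
    # never reached 50% kill within dosing
    DrugProfile("inactive", ec50={2: 30.0}, ic50=None, cmax=100.0, maxdose=10_000.0),
]

print("drug              score  profile(K0..K3)  excluded")
for d in drugs:
    y = scale_sensitivity(d.ic50, d.cmax, d.maxdose, cfg) if d.maxdose else 0.0
    b = binarize_targets(d, cfg, n=4)
    print(f"{d.drug_id:<17} {y:5.2f}  {''.join(map(str, b.dtip.tolist())):^15}  {b.excluded}")

print(
    "\nScore 1 means effective at a clinically safe dose, 0 means no kill "
    "within dosing; a profile bit 1 marks a kinase whose EC50 falls inside "
    "the drug's IC50 window, i.e. a plausible mechanism of the kill."
)
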