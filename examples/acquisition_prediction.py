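"""The Learning Rate Law: reinforcements-to-acquisition from informativeness.

One constant k (the informativeness yielding one-shot acquisition) links
acquisition speed across protocols: RtoAcq = k/(iota - 1).  Estimating k
from one group predicts the other despite a tenfold ITI difference.
"""

from iotalearn import (
    LearningRateParams,
    estimate_k,
    learning_rate,
    reinforcements_to_acquisition,
)

# trace conditioning in head-fixed mice: two groups, iota = 60 and 600
k60 = estimate_k(92, 60)     # from the iota=60 group's median RtoAcq
k600 = estimate_k(8.5, 600)  # from the iota=600 group's median RtoAcq
print(f"k estimated from the iota=60  group: {k60:.0f}")
print(f"k estimated from the iota=600 group: {k600:.0f}")

params = LearningRateParams(k_learn=k60)
pred = reinforcements_to_acquisition(600, params)
print(f"iota=600 acquisition predicted from the iota=60 group's k: "
      f"{pred:.1f} reinforcements (observed median 8.5)")

# crowding trials defeats its purpose: a 5-s CS with a 5-s ITI has
# informativeness (5+5)/5 = 2, far from the well-spaced iota = 240
spaced = LearningRateParams(k_learn=250.0)
print()
for iota, label in ((240.0, "20-min spacing (iota 240)"),
                    (2.0, "5-s spacing   (iota 2)")):
    alpha = learning_rate(iota, spaced)
    rto = reinforcements_to_acquisition(iota, spaced)
    print(f"{label}: learning rate {alpha:.3f}, "
          f"~{rto:.0f} reinforcement(s) to acquisition")
print()
print("Crowding trials multiplies the reinforcements required ~240-fold;")
print("what matters is relative, not absolute, temporal separation.")
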