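"""The five-step moderation analysis of statin effects on gait speed reserve.

For each candidate moderator: overlap screen, per-level propensity
weighting, balance check, and the PS-weighted interaction model
Y = b0 + (b1 + b3*M)X + b2*M.  Prints the moderated average treatment
effects (M-ATE) per moderator level and the interaction coefficient b3.
"""

from gaitmod import CohortSpec, generate_cohort
from gaitmod.moderation import results_to_frame, run_all_moderators
from gaitmod.propensity import PSModelConfig

cohort = generate_cohort(CohortSpec(n=5519, seed=3), text=False)
moderators = ["aspirin", "acei", "beta_blocker", "thiazide"]
results = run_all_moderators(
    cohort, moderators, ps_config=PSModelConfig(method="logistic")
)

table = results_to_frame(results)
cols = ["beta3", "beta3_ci_low", "beta3_ci_high", "beta3_p", "m_ate_0", "m_ate_1"]
print(table[cols].round(2))

r = next(res for res in results if res.moderator == "aspirin")
print(
    f"\nAspirin: statin effect {r.m_ate_0.value:.1f} cm/s without aspirin, "
    f"{r.m_ate_1.value:.1f} cm/s with aspirin (interaction "
    f"{r.beta3.value:.1f} cm/s, p = {r.beta3.p_value:.3g})."
)

# The generating cohort carries a true aspirin x statin interaction of
# 5.76 cm/s on GSR: statins reduce reserve in aspirin non-users but not
# in concomitant aspirin users.  Other moderators' b3 estimates sit
# near zero; the identity m_ate_1 - m_ate_0 = beta3 holds exactly.
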