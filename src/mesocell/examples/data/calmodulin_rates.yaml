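# Cooperative two-lobe calcium-binding scheme for calmodulin.
#
# Provenance: rate constants of Faas, Raghavachari, Lisman & Mody (2011),
# "Calmodulin as a direct detector of Ca2+ signals", Nature Neuroscience
# 14:301-304 (measurements at 35 C).  Each lobe (N-terminal and
# C-terminal) binds two Ca2+ ions sequentially: the first ion binds while
# the lobe is in its tense (T) state; binding converts the lobe so the
# second ion binds the relaxed (R) state with much higher affinity
# (positive cooperativity).  Dissociation constants implied below:
#   N lobe: K_T = 193 uM, K_R = 0.788 uM
#   C lobe: K_T = 27.8 uM, K_R = 0.264 uM
# Statistical factors (x2 on the first association and on dissociation
# from the doubly-occupied lobe) are applied by the model builder and are
# NOT included in these per-site constants.
n_lobe:
  k_on_T: 7.7e8     # M^-1 s^-1
  k_off_T: 1.486e5  # s^-1
  k_on_R: 3.2e10    # M^-1 s^-1
  k_off_R: 2.522e4  # s^-1
c_lobe:
  k_on_T: 8.4e7     # M^-1 s^-1
  k_off_T: 2.335e3  # s^-1
  k_on_R: 2.5e7     # M^-1 s^-1
  k_off_R: 6.6      # s^-1
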