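"""Expected-gain landscape of the bead task.

For each cost x evidence condition, prints the probability of a correct
majority judgment, the expected gain (100 - n*c) * p(n|q), and the
reward-maximizing sample count.  Low evidence with high cost makes
sampling barely worthwhile (optimal n = 1), while costless sampling
rewards drawing almost to the cap.
"""

from beadtask import ALL_CONDITIONS, gain_profile

for cond in ALL_CONDITIONS:
    gp = gain_profile(cond)
    print(f"\n{cond.label}  (c={cond.c}, q={cond.q})")
    print("   n  p(correct)  E[gain]")
    for n in range(0, 21, 4):
        print(f"  {n:2d}   {gp.p_correct[n]:.3f}     {gp.expected_gain[n]:6.2f}")
    print(f"  optimal n = {gp.optimal_n}, max expected gain = {gp.max_gain:.2f} credits")
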