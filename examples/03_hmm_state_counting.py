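"""Count and decode hidden conformational states with a Gaussian HMM.

A molecule hops among three states whose observed levels are blurred by
thermal noise. Expectation-maximization with random restarts fits HMMs of
increasing size; the AIC minimum picks the state count, and the Viterbi
path idealizes the trace.
"""

import numpy as np

from steptrace import (MarkovParams, add_gaussian_noise, gen_markov_states,
                       hmm_fit, select_states, states_to_levels, viterbi)

P = np.full((3, 3), 0.01)
np.fill_diagonal(P, 0.98)
seq = gen_markov_states(MarkovParams(P, np.full(3, 1 / 3)), 5000, seed=0)
trace = add_gaussian_noise(states_to_levels(seq, [0.0, 3.0, 6.0]), 0.5,
                           seed=1)

K_star, reports = select_states(trace, K_max=5, n_restarts=3, seed=2,
                                tol=1e-6, max_iter=200)
print("AIC by state count:",
      {r.n_states: round(r.aic, 1) for r in reports})
print(f"selected K = {K_star} (true K = 3)")

params, report = hmm_fit(trace, K_star, n_restarts=3, seed=3)
print(f"fitted means: {np.round(np.sort(params.means), 2)} "
      f"(true 0, 3, 6)")
path = viterbi(trace, params)
order = np.argsort(params.means)
accuracy = np.mean(order[path.labels - 1] + 1 == seq.labels)
print(f"Viterbi label accuracy vs ground truth: {accuracy:.3f}")
print("-> AIC finds the true state count and the decoded path tracks the "
      "hidden sequence almost perfectly at this separation.")
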