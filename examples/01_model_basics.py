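"""The many-facet Rasch model: probabilities, likelihood, sampling.

Evaluates the adjacent-categories model for one examinee/task/rater
combination, then samples ratings and recovers their empirical mean.
"""
import numpy as np

import facetlink as fl

# a middling examinee rated by a severe rater on an easy task
theta, beta, gamma = 0.4, -0.3, 0.8
eta = theta - beta - gamma
d = (0.0, -0.9, -0.2, 0.3, 0.8)  # category transitions, harder with k

probs = fl.category_probabilities(eta, d)
print(f"eta = theta - beta - gamma = {eta:+.2f}")
print("P(score = k):", np.round(probs, 4))
# the distribution leans low because the rater's severity outweighs the easy task

rng = np.random.default_rng(0)
scores = fl.sample_response(np.full(5000, eta), d, 5, rng)
print(f"mean sampled score {scores.mean():.3f} vs model expectation "
      f"{np.dot(probs, np.arange(1, 6)):.3f}")

params = fl.MFRMParameters(theta=[theta], beta=[beta], gamma=[gamma], d=d, K=5)
data = fl.RatingDataset(examinee=[0], task=[0], rater=[0], score=[2], J=1, I=1, R=1, K=5)
print(f"log-likelihood of one observed score of 2: {fl.log_likelihood(params, data):.4f}")
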