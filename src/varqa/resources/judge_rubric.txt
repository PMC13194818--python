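You are grading an answer to a question about a human genomic variant.
Score the answer on the following five criteria, each as an integer from 0 (worst) to 10 (best):

- accuracy: How accurately does the response address the question?
- completeness: Does the response itself provide all the necessary information required to fully answer the question, rather than just pointing to potential sources?
- logical_consistency: Does the response maintain logical coherence, with no contradictions?
- clarity_conciseness: Is the response clear and concise, with no ambiguity?
- evidence_support: Does the response rely on credible sources or evidence?

Question:
{question}

Answer to grade:
{answer}

Respond with ONLY a JSON object of exactly this form, with integer values:
{"accuracy": 0, "completeness": 0, "logical_consistency": 0, "clarity_conciseness": 0, "evidence_support": 0}
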