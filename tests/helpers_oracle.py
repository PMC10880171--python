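"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid numpy/scipy and the package's own vector code:
plain dictionaries of counts and explicit loops, so they can disagree with
the implementation if either is wrong.
"""

import math


def oracle_ngrams(text, n_values):
    counts = {}
    for n in sorted(n_values):
        for i in range(len(text) - n + 1):
            gram = text[i : i + n]
            counts[gram] = counts.get(gram, 0) + 1
    return counts


def oracle_tfidf_vector(text, idf, n_values):
    counts = oracle_ngrams(text, n_values)
    total = sum(counts.values())
    vec = {}
    for gram, count in counts.items():
        if gram in idf and total:
            weight = (count / total) * idf[gram]
            if weight != 0.0:
                vec[gram] = weight
    return vec


def oracle_idf(dict_terms, n_values, dialect):
    df = {}
    for term in dict_terms:
        for gram in oracle_ngrams(term, n_values):
            df[gram] = df.get(gram, 0) + 1
    n_docs = len(dict_terms)
    if dialect == "paper":
        return {g: math.log(n_docs / d) for g, d in df.items()}
    return {g: math.log((1 + n_docs) / (1 + d)) + 1.0 for g, d in df.items()}


def oracle_cosine(a, b):
    norm_a = math.sqrt(sum(x * x for x in a.values()))
    norm_b = math.sqrt(sum(x * x for x in b.values()))
    if norm_a == 0.0 or norm_b == 0.0:
        return 0.0
    return sum(v * b.get(g, 0.0) for g, v in a.items()) / (norm_a * norm_b)


def oracle_score_matrix(query_texts, dict_terms, n_values, dialect="paper"):
    """Dictionary-of-counts implementation of the TF-IDF cosine matrix."""
    idf = oracle_idf(dict_terms, n_values, dialect)
    dict_vecs = [oracle_tfidf_vector(t, idf, n_values) for t in dict_terms]
    out = []
    for q in query_texts:
        qv = oracle_tfidf_vector(q, idf, n_values)
        out.append([oracle_cosine(qv, dv) for dv in dict_vecs])
    return out


def oracle_marginal_probability(pool_scores, positives):
    """Softmax-and-sum with explicit loops; pool_scores are combined scores."""
    m = max(pool_scores)
    weights = [math.exp(s - m) for s in pool_scores]
    total = sum(weights)
    return sum(w for w, p in zip(weights, positives) if p) / total


def random_terms(rng, n_terms, alphabet="abcdef ", min_len=3, max_len=12):
    """Random canonical-ish strings over a tiny alphabet (may share n-grams)."""
    terms = []
    while len(terms) < n_terms:
        length = int(rng.integers(min_len, max_len + 1))
        chars = [alphabet[int(i)] for i in rng.integers(0, len(alphabet), length)]
        term = "".join(chars)
        term = " ".join(term.split())  # collapse whitespace, canonical form
        if term:
            terms.append(term)
    return terms
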