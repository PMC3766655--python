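"""Zipf's law in ordinary text: tokenize a passage and fit the rank-frequency law.

Builds a small corpus in memory, strips punctuation and case, counts word
frequencies, and fits ln(frequency) = -a ln(rank) + ln(beta) by OLS.
"""

from carelex import build_vocabulary, fit_power_law, rank_frequency, tokenize_text

PASSAGE = """
The monkey strikes the keys of the typewriter at random; the words that
emerge are short and long, common and rare. The commonest word appears
again and again, the rarest appears once, and between them the frequency
of a word falls away as a power of its rank. The law holds for the epic
and the essay, for the poem and the prayer -- and, it turns out, for the
language of medical practice as well.
"""

stream = tokenize_text(PASSAGE, source_label="demo passage")
table = rank_frequency(build_vocabulary(stream.tokens))
fit = fit_power_law(table)

print(f"tokens: {table.total_tokens}, distinct words: {len(table)}")
print("top of the rank-frequency table:")
for rank, word, count in table.rows[:5]:
    print(f"  rank {rank}: {word!r} x{count}")
print(f"log-log fit: slope {fit.slope:.3f}, R^2 {fit.r2:.3f} over {fit.n_points} ranks")
print("The slope estimates -a of the Zipf-like law f = beta * r^-a;")
print("text this short gives a rough fit, but the frequency decay is already visible.")
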