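"""Build a word graph from a short text and read off its four attributes.

Every unique word becomes a node and every consecutive word pair a directed
edge, so the graph encodes the trajectory of the discourse, not its meaning.
"""

import wordgraphs as wg

text = "I dreamed I was walking and walking and I saw the sea, the big sea."
tokens = wg.tokenize(text)
graph = wg.build_graph(tokens)
attrs = wg.attributes(graph)

print("tokens:", tokens)
print(f"N   = {attrs.N:>5d}   distinct words (lexical diversity)")
print(f"RE  = {attrs.RE:>5d}   edge instances on repeated word pairs "
      "(short-range recurrence)")
print(f"LSC = {attrs.LSC:>5d}   words in the largest mutually reachable set "
      "(long-range recurrence)")
print(f"ASP = {attrs.ASP:>7.3f} mean shortest directed path between "
      "reachable word pairs (graph size)")
print()
print("DOT representation (render with graphviz to inspect the loops):")
print(graph.to_dot())
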