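"""Build the inverted evidence index and run ranked triplet queries.

Scores come from the classifier in the real pipeline; here they are assigned
so the ranking is visible.  A disease-only query returns every gene and
chemical related to that disease, score-descending.
"""

from tripmine import InvertedIndex, Query, build_index, search
from tripmine.corpus_io import TripletRecord
from tripmine.search_index import EvidenceEntry, group_by_triplet

entries = [
    EvidenceEntry(TripletRecord("G1", "C1", "D1", 0.93, "doc1", 1, 2),
                  "CHEM1 increased GENE1 in cells.", "D1 patients improved."),
    EvidenceEntry(TripletRecord("G1", "C2", "D1", 0.71, "doc2", 0, 0),
                  "CHEM2 suppressed GENE1 in D1 patients.", "same sentence"),
    EvidenceEntry(TripletRecord("G2", "C1", "D2", 0.88, "doc3", 2, 3),
                  "CHEM1 induced GENE2 expression.", "A D2 cohort."),
    EvidenceEntry(TripletRecord("G1", "C1", "D1", 0.55, "doc4", 1, 1),
                  "CHEM1 weakly altered GENE1.", "D1 progression."),
]
index = build_index(entries)

print("disease-only query D1 (all genes/chemicals for the disease):")
for record, (rel, ctx), score in search(index, Query(diseases=["D1"])):
    print(f"  {score:.2f}  {record.gene_id} {record.chemical_id} "
          f"{record.disease_id}  <- {rel}")

dicts = {"chemical": {"C1": ["chemx", "compound X"]}}
results = search(index, Query(chemicals=["Compound X"], diseases=["D1"]),
                 dicts)
print("synonym query 'Compound X' + D1 ->", len(results), "pairs")

print("grouped by triplet (best score, evidence count):")
for triplet, best, n in group_by_triplet(search(index, Query(diseases=["D1"]))):
    print(f"  {triplet}  best={best:.2f}  n={n}")
# Queries are conjunctive across fields and disjunctive within a field;
# results are always sorted by classifier score, ties broken by document.
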