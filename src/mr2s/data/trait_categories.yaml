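# Trait-category vocabulary for the confounder screen (14 categories).
# The category column of the annotation table is matched against these names;
# anything else is routed to "uncategorized".  Edit or replace via
# confounder_screen(categories=...).
categories:
  - blood cell counts
  - body composition
  - serum lipids
  - diabetes
  - anthropometric
  - cardiovascular
  - autoimmune and inflammatory
  - skin and hair pigmentation
  - liver enzymes
  - kidney function
  - bone and mineral
  - respiratory
  - psychiatric and cognitive
  - reproductive and hormonal
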