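# Deposited genome records

The accession-dependent checks in `tests/test_acceptance.py`
(`TestDepositedAccessions`) compare the package's output against the
deposited *Boea hygrometrica* organellar genomes.  Those GenBank records
are not shipped with the package; download them here first:

```sh
# chloroplast (153,493 bp) and mitochondrial (510,519 bp) genomes
for acc in JN107811 JN107812; do
  curl -o ${acc}.gb "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=${acc}&rettype=gbwithparts&retmode=text"
done

# comparative mt panel for old/new insertion classification
mkdir -p panel
for acc in NC_005255 NC_001660 NC_010303 NC_007579 NC_011033 NC_008360 \
           NC_008362 NC_007982 NC_002511 NC_008285 NC_001284 NC_006581 \
           NC_012119; do
  curl -o panel/${acc}.gb "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=${acc}&rettype=gbwithparts&retmode=text"
done
```

Without these files the corresponding tests fail with a message pointing
back to this directory; all other tests are self-contained.
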