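##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth per allele">
##contig=<ID=geneA>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	high_pool	low_pool
geneA	10	toy01	C	T	.	PASS	.	GT:AD	./.:3,2	./.:3,2
geneA	20	toy02	C	T	.	PASS	.	GT:AD	./.:50,3	./.:50,2
geneA	30	toy03	C	T	.	PASS	.	GT:AD	./.:48,2	./.:48,2
geneA	40	toy04	C	T	.	PASS	.	GT:AD	./.:30,30	./.:30,30
geneA	50	toy05	C	T	.	PASS	.	GT:AD	./.:20,40	./.:40,20
geneA	60	toy06	C	T	.	PASS	.	GT:AD	./.:40,20	./.:20,40
geneA	70	toy07	C	T	.	PASS	.	GT:AD	./.:30,10	./.:30,10
geneA	80	toy08	C	T	.	PASS	.	GT:AD	./.:10,30	./.:35,5
geneA	90	toy09	C	T	.	PASS	.	GT:AD	./.:55,5	./.:10,30
geneA	100	toy10	C	T	.	PASS	.	GT:AD	./.:0,0	./.:0,0
geneA	110	toy11	C	T	.	PASS	.	GT:AD	./.:60,0	./.:30,30
geneA	120	toy12	C	T	.	PASS	.	GT:AD	./.:30,30	./.:60,0
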