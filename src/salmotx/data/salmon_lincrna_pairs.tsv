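module	lnc_id	lnc_coord	potential_function	lnc_tau	lnc_tau_tissue	direction	distance_bp	location	partner_gene	partner_coord	partner_tau	partner_tau_tissue
turquoise	MSTRG.73942	9:114446073-114467821:-	bi-directional promoter	0.92	it	antisense	82	upstream	tnfrsf11b	9:114463562-114520843:+	0.71	it
turquoise	MSTRG.12897	12:33141615-33147295:+	cis-acting	0.93	it	antisense	12253	downstream	axin2	12:33152650-33176973:-	0.78	it
turquoise	MSTRG.14606	12:86830932-86838832:+	cis-acting	0.84	it	sense	20245	downstream	tafa3	12:86669506-86815029:+	0.93	it
blue	MSTRG.73143	9:82359435-82369081:-	bi-directional promoter	0.99	mt	antisense	45	upstream	fgl1	9:82365126-82372703:+	0.84	mt
blue	MSTRG.66156	6:40516453-40525422:-	bi-directional promoter	0.71	mt	antisense	1540	upstream	mylk5	6:40521779-40556363:+	0.74	mt
blue	MSTRG.74622	9:133414489-133423849:-	bi-directional promoter	0.88	mt	antisense	1749	upstream	map6b	9:133421598-133432970:+	0.80	mt
blue	MSTRG.14788	12:93227925-93233836:-	bi-directional promoter	1.00	mt	antisense	2635	upstream	asic1b	12:93203192-93371283:+	1.00	mt
blue	MSTRG.66972	6:66295533-66309581:+	cis-acting	1.00	mt	antisense	4245	downstream	cnih3	6:66309826-66363982:-	1.00	mt
blue	MSTRG.15914	13:29057863-29064449:-	cis-acting	1.00	mt	antisense	7831	upstream	sema3gb	13:29052194-29099999:+	0.34	pt
blue	MSTRG.78212	CAJNNT020001653.1:166525-177677:+	cis-acting	0.98	mt	antisense	23812	downstream	ENSSSAG00000118817	CAJNNT020001653.1:192746-229722:-	1.00	mt
blue	MSTRG.74574	9:132125397-132133025:-	cis-acting	0.96	mt	antisense	25772	upstream	lrfn1	9:132152892-132292749:+	1.00	mt
blue	MSTRG.31322	18:23110600-23116380:-	cis-acting	0.96	mt	antisense	26353	upstream	chrm3a	18:23138733-23285523:+	0.82	mt
blue	MSTRG.78700	CAJNNT020001827.1:453935-461410:+	cis-acting	1.00	mt	sense	7726	downstream	fam46a	CAJNNT020001827.1:391685-610395:+	1.00	mt
blue	MSTRG.78214	CAJNNT020001653.1:171111-175419:-	cis-acting	0.97	mt	sense	21479	downstream	ENSSSAG00000118817	CAJNNT020001653.1:192746-229722:-	1.00	mt
green	MSTRG.37781	2:69192358-69198500:+	cis-acting	1.00	pt	antisense	775	downstream	ENSSSAG00000009504	2:69195275-69216886:-	1.00	pt
green	MSTRG.27861	16:86390879-86397670:+	cis-acting	1.00	pt	sense	1093	downstream	ENSSSAG00000099155	16:86296028-86394138:+	0.80	pt
brown	MSTRG.5662	10:30569004-30574706:-	cis-acting	0.99	ov	sense	1232	downstream	ENSSSAG00000054269	10:30571632-30586494:-	0.80	ov
brown	MSTRG.61464	4:83645855-83662828:-	cis-acting	0.49	pt	sense	14394	upstream	ENSSSAG00000094332	4:83629536-83635461:-	1.00	ov
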