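{"seed": 20240901, "cases": {"lmax1": {"signature": [[0, 2], [1, 2]], "tensor": [0.45474712467279, 0.9553914094496799, -0.9376243296594372, -0.3043313358728945, 0.8886776885533885, 0.9252746665246575, -0.4320888656622511, 1.8269715802430417], "rotation": [[-0.5805361843610344, -0.13596358723131444, -0.8028023677062271], [0.5303146700223872, 0.685024980638747, -0.4995068834960449], [0.6178544241215548, -0.7157196929301844, -0.3255783035543749]], "rotated_tensor": [0.45474712467279, 0.9553914094496799, -0.019001675977868525, 1.3192333188504841, -0.14410887009775503, 1.8185374539187358, 0.6072439332634549, -0.8395448085521413]}, "lmax4": {"signature": [[0, 1], [1, 1], [2, 1], [3, 1], [4, 1]], "tensor": [0.7145243648323221, -0.034036346010635724, 0.5602991674411499, -0.3044071966315117, 0.2312006767141988, -0.8571052850359501, -2.274552390391544, -0.5150660684086971, 0.6044988215437752, 0.4945501781307132, 0.06805721271831433, -0.8322640402333679, 0.601321794598111, 1.089255138815239, -0.2992425106413198, -0.5599124849815853, 0.36352861391811203, -1.089734481861684, 2.0110335346157417, 0.2986189594387649, 1.1794009507846244, -0.9414451654417698, -0.38770673868719935, 1.3270246580685625, -0.0013504640980436112], "rotation": [[-0.27160415845740704, 0.9620507297847565, -0.026259749223129847], [-0.7083903582610389, -0.21831236736436777, -0.6712099601306306], [-0.6514708600017665, -0.16370126320949163, 0.7408020079563609]], "rotated_tensor": [0.7145243648323221, -0.1530087034863501, 0.6189549593139151, 0.03522025332380861, 0.4750448828728275, 2.365494679641201, 0.1263491163981218, -0.3755345560924472, 0.7836840288475497, 0.23506534694913228, 1.325985786083796, -0.03515310590922671, -0.7997979143891757, -0.3032921550323979, -0.576618218052172, -0.11877144868262648, -0.035958357191383954, 0.48553467391173266, -0.2234585210940494, -1.0646690876352685, 0.21295257353812616, -2.466541796841287, -0.869223611406568, -0.9804489350980653, 0.6125552250889261]}, "lmax10": {"signature": [[0, 1], [1, 1], [2, 1], [3, 1], [4, 1], [5, 1], [6, 1], [7, 1], [8, 1], [9, 1], [10, 1]], "tensor": [-0.8186738758317484, -0.7063242624938614, 0.7162774550816587, -0.6689698698080822, 2.130390818956996, -0.2749704470189921, -1.53690197279378, -0.8424346917567687, 0.5502240688596407, 1.1009085881354956, -0.11591189011878432, -0.44460867945362115, 0.27357702610739076, 0.9995351817430544, 1.3302793133677169, -0.4595369355252388, -0.9594320753199086, -0.34215133114078466, -2.5085769583920468, -0.23837951072698332, 0.16473476359342318, -1.6244578684655064, 1.475834385451884, 0.08607950386922811, -0.4972166235247395, -0.17181385760424908, -0.3784183368083849, 0.56506414268104, -0.15365099510169386, 0.24055083880259256, -0.1541213394849293, 0.5912790454292238, -0.47843042096006105, 1.0167733871480316, -0.3176936711848128, 0.22114619282458656, 0.937963946151605, -0.4321180773333614, 0.25764058846060284, -0.42072723447820504, 1.930936069837121, 2.019347897695858, 0.1771333412233729, 0.6850427475980647, -0.7735000989603332, 0.750089348437053, 0.15076639514825385, -0.6822910466764246, -0.1656745850903027, 0.6392846254053743, -1.3439818530305703, 0.28795075839083906, 1.0844310598491407, -0.1623069740053075, 1.0289591399864717, 0.027191997585828673, 0.21493694602153873, -1.4827267761049492, -1.2651938200572663, -0.04889780934078652, -1.3000305008755555, 0.4892012699933146, 0.643514480766079, 1.8393112066370843, 0.22092602782881413, 1.575784871926562, 0.056214182042934976, -1.6191512544585045, 0.06559765569806687, -1.594757322585135, 0.1535388871433329, -0.5931337122256005, -1.4021150117188301, 1.2316770367084844, 0.899288959285873, -0.5214122671117124, -0.3183461789834047, -0.16838312969219568, -1.3028692917365317, -1.1583502485591297, 0.15230306043501415, 1.1732435770161653, -0.8535490933533021, 1.0582306558686885, 0.6262807027099784, -0.9133817879991694, -0.8804563973567965, -0.25918815163112635, 1.7125040255983768, 0.018108044030287828, 0.1431578992416559, 1.5088387944582113, 0.6052945812738848, 1.0733366199889343, -1.1676279774223912, -0.9011203754317579, 2.1311832135420383, 1.789071017807747, 0.038585684122782266, 0.010578773113045116, -1.1035342600710691, 1.3853056020115722, 1.440901446238445, -0.8912919063400317, 0.8583214792888698, 0.38806597800044157, -0.34331774797046605, -1.0989330705647673, 1.0591975001562164, 0.870917782724236, -0.8792862351879162, 0.8920278952133078, 1.0330403303685727, -2.4174980785378133, -2.1646741046043556, 1.7624509532197474, -0.38497721273705815, 0.07851814081207714, 0.9873926487745521, 0.04794466059308605, -0.2267817711356451], "rotation": [[-0.10184650692143121, 0.42111495581022346, 0.9012710374914178], [0.4041261187215999, 0.8453708245467655, -0.3493282828116517], [-0.9090156044837284, 0.32864930092436767, -0.2562816181605818]], "rotated_tensor": [-0.8186738758317484, -1.1176700946094311, 0.19240233025019685, 0.4162486589610055, 0.2928480664459762, -2.03659507738603, -0.44286420638665464, 0.3192537449647781, -1.8593420986490345, -0.8888813913548396, -0.47212281348721796, -0.13056979876879865, 0.862880444452824, 1.5993936798445956, -0.3465094492434694, 0.1584115676499234, -2.2987541093619757, 0.15317589870567927, -0.5516602992271028, 1.0284321832552519, 0.6857258242054588, -1.825162256397877, 0.17289141271702493, 1.4064255592043808, -0.08358269384190889, -0.018518804515474302, 0.050995947797799035, -0.19369415300120882, -0.3219017647112762, 0.005986240332147341, -0.3478808442115779, -0.20019259575697554, -0.28471577314358604, 0.592276082340518, 0.5205374583902835, 1.1624909809540318, 0.3896799130417402, 0.9819062977105264, 0.45919434049327634, 0.0471825542510059, -0.3039471800015651, 1.1760235153630838, -0.4421340269797835, -0.9799721887898474, -0.30066294896118895, 0.6742480726785285, 0.3847097778701829, -1.6073777636912006, 2.0140694094263645, 0.5638875862402735, -1.0981334282689932, 0.4657084610234153, -2.3909315000008133, -1.52313925022773, -0.4653836497721518, 1.5638745136740275, 0.8147021787289598, 0.32827329200168853, -0.3091305415617738, 0.4374922389956591, -0.16936250855242105, 0.0035471267089471348, 0.10807396960979244, 0.7718108771249158, 1.0131897200216782, 0.30730082659004276, -1.0603728477383394, 0.9316384033949752, -0.9453606783833783, -0.6260524214636337, -0.5202732941280462, 1.8611519098938962, -0.5458649509422696, -0.752331324510251, -0.6967562840983842, 0.04741604748395685, -1.777477171993121, 0.862510045568846, -0.8173997949872406, 0.7622534637987495, 1.0943395533073226, -0.3178603476219181, 1.2428452006593544, -0.5729751730947849, 0.3693850829414188, 0.36555768274305556, -1.6247472260680802, 1.1824902665459383, -1.6957332991242684, -0.12939508132633015, -0.6467877144917183, -2.379477762312373, -1.3465510221962793, 0.596501902761029, 0.5063488726061631, -1.0747335607281001, -1.0540768454968505, -1.0759608234195488, 0.3749187283625608, 0.847070130124106, -0.6870316743798109, -1.2369233883527342, -0.6504198951580418, -0.0721686549535023, 2.4880254640273916, -0.5440915611148106, 0.10331091193860446, -0.26713465648471274, -2.0258453706181783, 0.15282591158280454, -0.5726572138433292, 0.6644453004409733, -1.7356582069795246, -0.05627453712071576, 1.3167496228542848, -1.7363420769099784, -1.8659209120831102, 1.0424916801564614, 1.1000598022169803, -0.32908909548957904, 0.0970593927584524]}}}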